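"""Maximum-likelihood fitting of the SHM-indel model.

The repertoire log-likelihood ``sum_s log L(s; theta)`` is maximized over
``theta = (P(mu), phi)`` with ``phi = (beta_del, beta_ins, P_del, P_ins)``
by alternating two moves per iteration:

* an exact EM update of the age prior ``P(mu)``: the new naive fraction is
  the repertoire average of the per-sequence posterior naive weights, and
  the new smooth density is the posterior-weight-weighted average of the
  per-sequence age posteriors;
* a numerical gradient-ascent step on ``phi`` with momentum and a
  projection onto the constraint set (rates >= 0, length distributions on
  the probability simplex).  The gradient of ``sum_s <log L(s|mu_s; phi)>``
  over the age posterior is approximated by a single Monte-Carlo age
  sample per sequence per iteration (slowly moving parameters make the
  iteration average stand in for a large sample) and finite differences.

Per-sequence age posteriors are evaluated on a small set of nodes placed
around the current posterior maximum and interpolated with a monotone
piecewise cubic in log-likelihood, then combined with the binned prior on
the full mu grid.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.special import erfinv, logsumexp

from .annotate import (
    DEFAULT_PENALTIES,
    DeterministicAnnotation,
    PenaltySet,
    annotate_repertoire,
)
from .core import (
    DEFAULT_MU_BIN_WIDTH,
    IndelModel,
    LengthDistribution,
    MuPrior,
    NucleotideSequence,
    TemplateSet,
)
from .likelihood import (
    PruningConfig,
    _batch_eval,
    _batch_scales,
    _build_edges,
    _eq_matrix,
    build_pruning_mask,
    log_forward_sum,
    passage_posterior,
)

logger = logging.getLogger("shmindel")


class GradientError(RuntimeError):
    """Raised when a finite-difference gradient component is not computable."""


class DegenerateSequenceError(ValueError):
    """Raised when a read has zero posterior mass everywhere."""


@dataclass
class OptimizerConfig:
    """Knobs of the EM + gradient-ascent optimizer."""

    T: int = 200                 # maximum number of iterations
    alpha0: float = 0.005        # base learning rate (per-component scaled)
    epsilon: float = 1e-4        # finite-difference step
    n_mc: int = 1                # Monte-Carlo age samples per sequence per iteration
    convergence_tol: float = 1e-6  # relative log-likelihood change over the window
    convergence_window: int = 10
    omega0: float = 1.0          # momentum prefactor
    scale_floor: float = 1e-3    # floor of the per-component learning-rate scale
    gradient_clip: float = 2.0   # cap on length-probability gradient components
    seed: int = 0
    nodes_low: int = 15          # posterior nodes for lightly mutated reads (< 5 SHM)
    nodes_high: int = 25         # posterior nodes for heavily mutated reads
    posterior_mode: str = "nodes"  # "nodes" (interpolated) or "grid" (exact quadrature)

    def __post_init__(self) -> None:
        if self.T < 1 or self.epsilon <= 0 or self.n_mc < 1:
            raise ValueError("invalid optimizer configuration")

    def learning_rate(self, t: int) -> float:
        return self.alpha0 * np.exp(-2.0 * t / self.T)

    def momentum(self, t: int) -> float:
        return self.omega0 * t / (t + 3.0)


@dataclass
class SequencePosterior:
    """Posterior over the maturation age of one sequence.

    ``f_s`` is the posterior probability of being naive (``mu = 0``);
    ``grid_density`` is the smooth part on the prior's mu bins and
    integrates to 1; ``nodes``/``values`` sample it at the evaluation
    nodes; ``marginal_loglik`` is ``log L(s; theta)``.
    """

    f_s: float
    nodes: np.ndarray
    values: np.ndarray
    grid_density: np.ndarray
    loglik_nodes: np.ndarray
    marginal_loglik: float
    map_mu: float
    spread: float
    interpolant: PchipInterpolator | None = None


# ---------------------------------------------------------------------------
# posterior computation
# ---------------------------------------------------------------------------

def place_nodes(
    center: float, spread: float, n_nodes: int, prior: MuPrior
) -> np.ndarray:
    """Evaluation nodes: Gauss-like spacing around the posterior maximum.

    ``n_nodes`` total, two of which are mandatory endpoints at the lowest
    and highest prior bin centers (mu ~ 0 and mu ~ 1).
    """
    lo = prior.bin_width / 2.0
    hi = 1.0 - prior.bin_width / 2.0
    n_inner = max(n_nodes - 2, 3)
    q = np.linspace(-0.999, 0.999, n_inner)
    z = np.sqrt(2.0) * erfinv(q)
    z = z / z[-1] * 4.0  # span center +/- 4 spreads
    inner = np.clip(center + spread * z, lo, hi)
    nodes = np.unique(np.concatenate(([lo, hi], inner)))
    # drop near-duplicates produced by clipping
    keep = np.concatenate(([True], np.diff(nodes) > 1e-12))
    return nodes[keep]


def posterior_from_loglik(
    nodes: np.ndarray,
    loglik_nodes: np.ndarray,
    loglik0: float,
    prior: MuPrior,
) -> SequencePosterior:
    """Combine conditional log-likelihoods with the prior (the E step).

    ``loglik_nodes[k] = log L(s | mu = nodes[k]; phi)`` and ``loglik0`` is
    the exact-naive value ``log L(s | 0; phi)``.  The log-likelihood is
    interpolated onto the prior grid with a monotone piecewise cubic
    before the quadrature, unless the nodes already are the grid.
    """
    nodes = np.asarray(nodes, dtype=float)
    ll = np.asarray(loglik_nodes, dtype=float)
    centers = prior.centers
    h = prior.bin_width
    interp = None
    if len(nodes) == len(centers) and np.allclose(nodes, centers):
        llg = ll.copy()
    else:
        if len(nodes) < 2:
            raise ValueError("need at least two nodes to interpolate")
        finite = np.isfinite(ll)
        if not finite.any():
            llg = np.full(len(centers), -np.inf)
        else:
            floor = ll[finite].max() - 745.0
            interp = PchipInterpolator(nodes, np.maximum(ll, floor))
            llg = np.asarray(interp(np.clip(centers, nodes[0], nodes[-1])))
    with np.errstate(invalid="ignore", divide="ignore"):
        logw = np.where(prior.density > 0, llg + np.log(prior.density), -np.inf)
    if np.all(np.isinf(logw)) and (not np.isfinite(loglik0) or prior.f == 0.0):
        raise DegenerateSequenceError("zero posterior mass everywhere")
    log_smooth = logsumexp(logw) + np.log(h) if np.any(np.isfinite(logw)) else -np.inf
    # posterior naive weight, Bayes between the delta and the smooth part
    terms = []
    if prior.f > 0 and np.isfinite(loglik0):
        terms.append(np.log(prior.f) + loglik0)
    else:
        terms.append(-np.inf)
    if prior.f < 1 and np.isfinite(log_smooth):
        terms.append(np.log1p(-prior.f) + log_smooth)
    else:
        terms.append(-np.inf)
    marginal = logsumexp(terms)
    if not np.isfinite(marginal):
        raise DegenerateSequenceError("sequence likelihood is zero under the model")
    f_s = float(np.exp(terms[0] - marginal))
    if np.isfinite(log_smooth):
        grid_density = np.exp(logw - log_smooth)
        grid_density /= grid_density.sum() * h
        mean = float((centers * grid_density).sum() * h)
        sd = float(np.sqrt(max(((centers - mean) ** 2 * grid_density).sum() * h, 0.0)))
        map_mu = float(centers[int(np.argmax(grid_density))])
    else:
        grid_density = np.zeros(len(centers))
        map_mu, sd = 0.0, h
    values = np.zeros(len(nodes))
    if np.isfinite(log_smooth):
        node_dens = np.interp(nodes, centers, prior.density)
        with np.errstate(invalid="ignore", divide="ignore"):
            values = np.where(
                node_dens > 0, np.exp(ll + np.log(node_dens) - log_smooth), 0.0
            )
        values[~np.isfinite(values)] = 0.0
    return SequencePosterior(
        f_s=f_s,
        nodes=nodes,
        values=values,
        grid_density=grid_density,
        loglik_nodes=ll,
        marginal_loglik=float(marginal),
        map_mu=map_mu,
        spread=max(sd, 2 * h),
        interpolant=interp,
    )


def compute_posterior(
    s: NucleotideSequence,
    t_star: NucleotideSequence,
    theta: IndelModel,
    mask: np.ndarray | None = None,
    center: float | None = None,
    spread: float | None = None,
    n_nodes: int = 15,
    exact_grid: bool = False,
) -> SequencePosterior:
    """Age posterior of one read (standalone; the fit loop uses a batched path).

    With ``exact_grid`` the conditional likelihood is evaluated at every
    prior bin center (exact quadrature, no interpolation).
    """
    prior = theta.prior
    if exact_grid:
        nodes = prior.centers
    else:
        if center is None or spread is None:
            raise ValueError("center and spread are required unless exact_grid=True")
        nodes = place_nodes(center, spread, n_nodes, prior)
    ll = np.array([log_forward_sum(s, t_star, float(m), theta, mask) for m in nodes])
    ll0 = 0.0 if s.seq == t_star.seq else -np.inf
    return posterior_from_loglik(nodes, ll, ll0, prior)


# ---------------------------------------------------------------------------
# M step: prior update (closed form) and phi update (projected gradient)
# ---------------------------------------------------------------------------

def em_update_prior(
    posteriors: list[SequencePosterior], previous: MuPrior | None = None
) -> MuPrior:
    """Closed-form EM update of the age prior.

    The new naive fraction is the mean posterior naive weight; the new
    smooth density is the average of the per-sequence smooth posteriors
    weighted by their experienced weight ``1 - f_s``.
    """
    if not posteriors:
        raise ValueError("need at least one posterior")
    f_new = float(np.mean([p.f_s for p in posteriors]))
    weights = np.array([1.0 - p.f_s for p in posteriors])
    wsum = weights.sum()
    bin_width = previous.bin_width if previous is not None else DEFAULT_MU_BIN_WIDTH
    if wsum <= 0:
        if previous is None:
            raise ValueError("all sequences are posterior-naive and no previous prior given")
        warnings.warn("all sequences posterior-naive; keeping previous smooth density")
        return MuPrior(f=f_new, density=previous.density, bin_width=previous.bin_width)
    dens = np.zeros_like(posteriors[0].grid_density)
    for w, p in zip(weights, posteriors):
        if w > 0:
            dens += w * p.grid_density
    dens /= wsum
    n_bins = len(dens)
    h = 1.0 / n_bins
    dens = dens / (dens.sum() * h)
    return MuPrior(f=f_new, density=dens, bin_width=h)


def draw_mu_samples(
    posteriors: list[SequencePosterior],
    config: OptimizerConfig | None = None,
    rng: np.random.Generator | int = 0,
) -> np.ndarray:
    """One age sample per sequence per MC round, shape ``(n_mc, N)``.

    Sampling is by inverse CDF on the mixture: mass ``f_s`` at exactly 0,
    the binned smooth posterior elsewhere (with uniform jitter inside the
    sampled bin).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n_mc = config.n_mc if config is not None else 1
    n = len(posteriors)
    out = np.zeros((n_mc, n))
    for si, p in enumerate(posteriors):
        h = 1.0 / len(p.grid_density)
        cdf = None
        for k in range(n_mc):
            if rng.random() < p.f_s:
                out[k, si] = 0.0
                continue
            if cdf is None:
                cdf = np.cumsum(p.grid_density)
                if cdf[-1] <= 0:
                    raise DegenerateSequenceError(
                        "cannot sample an experienced age from an all-naive posterior"
                    )
                cdf = cdf / cdf[-1]
            idx = int(np.searchsorted(cdf, rng.random()))
            out[k, si] = (idx + rng.random()) * h
    return out


def project_simplex(raw: np.ndarray) -> np.ndarray:
    """Euclidean projection onto the probability simplex (sort-and-threshold)."""
    v = np.asarray(raw, dtype=float)
    if v.ndim != 1 or len(v) < 1:
        raise ValueError("expected a 1-D vector")
    u = np.sort(v)[::-1]
    css = np.cumsum(u) - 1.0
    ks = np.arange(1, len(v) + 1)
    cond = u - css / ks > 0
    rho = int(np.nonzero(cond)[0][-1])
    tau = css[rho] / (rho + 1)
    return np.maximum(v - tau, 0.0)


def clip_rates(beta: float) -> float:
    """Projection of a rate ratio onto its constraint set (non-negativity)."""
    return max(float(beta), 0.0)


def project_phi(raw: np.ndarray, theta_max: int) -> np.ndarray:
    out = np.empty_like(raw)
    out[0] = clip_rates(raw[0])
    out[1] = clip_rates(raw[1])
    out[2 : 2 + theta_max] = project_simplex(raw[2 : 2 + theta_max])
    out[2 + theta_max :] = project_simplex(raw[2 + theta_max :])
    return out


def momentum_step(
    phi_t: np.ndarray,
    phi_prev: np.ndarray,
    gradient: np.ndarray,
    t: int,
    config: OptimizerConfig,
    theta_max: int | None = None,
) -> np.ndarray:
    """phi_{t+1} = Proj(phi_t + alpha_t * gradient + omega_t * (phi_t - phi_prev)).

    The learning rate decays as ``exp(-2t/T)``.  The two rate components
    are additionally scaled by their own magnitude (floored) so they move
    at a sensible relative speed; the length-distribution components use
    one uniform scale per block — a *non*-uniform scale inside a simplex
    block would shift the projected-gradient fixed point away from the
    maximum-likelihood solution, because the simplex projection subtracts
    a common threshold from every component.
    """
    if t < 1:
        raise ValueError("iteration index starts at 1")
    phi_t = np.asarray(phi_t, dtype=float)
    if theta_max is None:
        theta_max = (len(phi_t) - 2) // 2
    scale = np.ones_like(phi_t)
    scale[0] = max(abs(phi_t[0]), config.scale_floor)
    scale[1] = max(abs(phi_t[1]), config.scale_floor)
    raw = (
        phi_t
        + config.learning_rate(t) * scale * np.asarray(gradient, dtype=float)
        + config.momentum(t) * (phi_t - np.asarray(phi_prev, dtype=float))
    )
    return project_phi(raw, theta_max)


# ---------------------------------------------------------------------------
# batched pruned evaluation over a repertoire
# ---------------------------------------------------------------------------

@dataclass
class _SeqWorkspace:
    read: NucleotideSequence
    template: NucleotideSequence
    annotation: DeterministicAnnotation
    exact0: bool
    center: float
    spread: float
    n_nodes: int


@dataclass
class _Batch:
    """Concatenated pruned-DP geometries for a whole repertoire.

    Evaluations run in linear space against fixed per-sequence row
    scales; :meth:`refresh_scales` recomputes the scales (and per-edge
    scale factors) at per-sequence reference ages, which the fit loop
    does once per iteration.  Evaluations that leave the representable
    range automatically fall back to an exact log-sum-exp sweep.
    """

    theta_max: int
    rp_ptr: np.ndarray      # offsets into row_ptr, one slice per sequence
    row_ptr: np.ndarray     # per-sequence row -> local cell ranges
    ep_ptr: np.ndarray      # offsets into eptr_rel, one slice per sequence
    eptr_rel: np.ndarray    # per-sequence local cell -> local edge ranges
    edge_base: np.ndarray   # absolute offset of each sequence's edges
    esrc: np.ndarray
    etype: np.ndarray
    edr: np.ndarray
    edst: np.ndarray        # destination row (read index) of each edge
    c_ptr: np.ndarray       # offsets of per-sequence row-scale vectors
    n_seq: int
    c_all: np.ndarray = None
    cfin: np.ndarray = None
    ffac: np.ndarray = None

    def refresh_scales(self, model: IndelModel, mu_ref: np.ndarray) -> None:
        if self.c_all is None:
            self.c_all = np.zeros(int(self.c_ptr[-1]))
            self.cfin = np.zeros(self.n_seq)
            self.ffac = np.ones(len(self.esrc))
        _batch_scales(
            np.ascontiguousarray(mu_ref, dtype=np.float64),
            float(model.beta_del),
            float(model.beta_ins),
            np.ascontiguousarray(model.len_del.probs),
            np.ascontiguousarray(model.len_ins.probs),
            self.rp_ptr,
            self.row_ptr,
            self.ep_ptr,
            self.eptr_rel,
            self.edge_base,
            self.esrc,
            self.etype,
            self.edr,
            self.edst,
            self.c_ptr,
            self.c_all,
            self.cfin,
            self.ffac,
        )

    def evaluate(
        self,
        seq_idx: np.ndarray,
        mus: np.ndarray,
        beta_del: float,
        beta_ins: float,
        pdel: np.ndarray,
        pins: np.ndarray,
    ) -> np.ndarray:
        out = np.empty(len(seq_idx))
        _batch_eval(
            np.ascontiguousarray(seq_idx, dtype=np.int64),
            np.ascontiguousarray(mus, dtype=np.float64),
            float(beta_del),
            float(beta_ins),
            np.ascontiguousarray(pdel, dtype=np.float64),
            np.ascontiguousarray(pins, dtype=np.float64),
            self.rp_ptr,
            self.row_ptr,
            self.ep_ptr,
            self.eptr_rel,
            self.edge_base,
            self.esrc,
            self.etype,
            self.edr,
            self.ffac,
            self.cfin,
            out,
        )
        return out

    def evaluate_phi(self, seq_idx, mus, phi: np.ndarray) -> np.ndarray:
        th = self.theta_max
        return self.evaluate(seq_idx, mus, phi[0], phi[1], phi[2 : 2 + th], phi[2 + th :])


def build_batch(
    reads: list[NucleotideSequence],
    templates: TemplateSet,
    init_model: IndelModel,
    annotations: list[DeterministicAnnotation] | None = None,
    penalties: PenaltySet = DEFAULT_PENALTIES,
    pruning: PruningConfig = PruningConfig(),
    mu_floor: float = 0.01,
) -> tuple[list[_SeqWorkspace], _Batch]:
    """Template selection, pruning masks and edge lists for every read.

    The unpruned forward/backward pass is run once per read at the
    deterministic-annotation age estimate (floored at ``mu_floor`` so the
    admissible band has some width) under ``init_model``; the resulting
    mask is reused for all subsequent evaluations.
    """
    if annotations is None:
        annotations = annotate_repertoire(reads, templates, penalties)
    theta = init_model.theta_max
    workspaces: list[_SeqWorkspace] = []
    rows, eptrs, esrcs, etypes, edrs, edsts = [], [], [], [], [], []
    rp_ptr = [0]
    ep_ptr = [0]
    edge_base = [0]
    c_ptr = [0]
    for s, ann in zip(reads, annotations):
        t = templates[ann.best_template]
        mu0 = float(np.clip(ann.shm_rate, mu_floor, 0.5))
        pp = passage_posterior(s, t, mu0, init_model)
        mask = build_pruning_mask(pp, pruning)
        row_ptr, eptr, esrc, etype, edr, edst = _build_edges(mask, _eq_matrix(s, t), theta)
        rows.append(row_ptr)
        rp_ptr.append(rp_ptr[-1] + len(row_ptr))
        eptrs.append(eptr)
        ep_ptr.append(ep_ptr[-1] + len(eptr))
        edge_base.append(edge_base[-1] + int(eptr[-1]))
        c_ptr.append(c_ptr[-1] + (len(row_ptr) - 1))
        esrcs.append(esrc)
        etypes.append(etype)
        edrs.append(edr)
        edsts.append(edst)
        h = init_model.prior.bin_width
        spread0 = float(
            np.sqrt(max(mu0 * (1 - mu0), 1e-4) / max(ann.n_aligned, 1)) + 2 * h
        )
        workspaces.append(
            _SeqWorkspace(
                read=s,
                template=t,
                annotation=ann,
                exact0=(s.seq == t.seq),
                center=float(ann.shm_rate),
                spread=spread0,
                n_nodes=15,
            )
        )
    batch = _Batch(
        theta_max=theta,
        rp_ptr=np.asarray(rp_ptr, dtype=np.int64),
        row_ptr=np.concatenate(rows).astype(np.int64),
        ep_ptr=np.asarray(ep_ptr, dtype=np.int64),
        eptr_rel=np.concatenate(eptrs).astype(np.int64),
        edge_base=np.asarray(edge_base, dtype=np.int64),
        esrc=np.concatenate(esrcs).astype(np.int32),
        etype=np.concatenate(etypes).astype(np.int16),
        edr=np.concatenate(edrs).astype(np.int16),
        edst=np.concatenate(edsts).astype(np.int32),
        c_ptr=np.asarray(c_ptr, dtype=np.int64),
        n_seq=len(reads),
    )
    batch.refresh_scales(
        init_model,
        np.array([max(ws.center, mu_floor) for ws in workspaces]),
    )
    return workspaces, batch


def numerical_gradient(
    phi: np.ndarray,
    mu_samples: np.ndarray,
    batch: _Batch,
    epsilon: float = 1e-4,
) -> np.ndarray:
    """Forward-difference gradient of the mean conditional log-likelihood.

    Component ``i`` is ``(sum_s,n log L(s|mu_s,n; phi + eps*e_i) -
    sum_s,n log L(s|mu_s,n; phi)) / (eps * N * n_mc)``; the ``1/(N*n_mc)``
    normalization (per-sequence mean rather than sum) is absorbed into the
    learning rate convention of :func:`momentum_step`.
    """
    mu_samples = np.atleast_2d(np.asarray(mu_samples, dtype=float))
    n_mc, n_seq = mu_samples.shape
    seq_idx = np.tile(np.arange(n_seq), n_mc)
    mus = mu_samples.reshape(-1)
    base = batch.evaluate_phi(seq_idx, mus, phi)
    if not np.all(np.isfinite(base)):
        bad = int(seq_idx[~np.isfinite(base)][0])
        raise GradientError(f"non-finite base log-likelihood for sequence index {bad}")
    base_sum = base.sum()
    grad = np.empty(len(phi))
    norm = epsilon * n_seq * n_mc
    for i in range(len(phi)):
        shifted = phi.copy()
        shifted[i] += epsilon
        ll = batch.evaluate_phi(seq_idx, mus, shifted)
        if not np.all(np.isfinite(ll)):
            raise GradientError(f"non-finite log-likelihood shifting phi component {i}")
        grad[i] = (ll.sum() - base_sum) / norm
    return grad


# ---------------------------------------------------------------------------
# initialization from deterministic annotations
# ---------------------------------------------------------------------------

def _smoothed_histogram(
    values: np.ndarray, sigmas: np.ndarray, grid: np.ndarray, floor_mix: float = 1e-4
) -> np.ndarray:
    dens = np.zeros(len(grid))
    for v, sd in zip(values, sigmas):
        dens += np.exp(-0.5 * ((grid - v) / sd) ** 2) / sd
    h = grid[1] - grid[0]
    total = dens.sum() * h
    if total <= 0:
        dens = np.ones(len(grid))
        total = dens.sum() * h
    dens = dens / total
    uniform = np.full(len(grid), 1.0 / (len(grid) * h))
    dens = (1 - floor_mix) * dens + floor_mix * uniform
    return dens / (dens.sum() * h)


def _smoothed_lengths(
    lengths: list[int], theta_max: int, sigma: float = 1.5, floor: float = 1e-6
) -> LengthDistribution:
    if not lengths:
        return LengthDistribution.geometric(10.0, theta_max)
    grid = np.arange(1, theta_max + 1, dtype=float)
    dens = np.zeros(theta_max)
    for ell in lengths:
        dens += np.exp(-0.5 * ((grid - ell) / sigma) ** 2)
    dens = dens / dens.sum()
    dens = np.maximum(dens, floor)
    return LengthDistribution(dens / dens.sum())


def initial_model_from_annotations(
    annotations: list[DeterministicAnnotation],
    theta_max: int,
    bin_width: float = DEFAULT_MU_BIN_WIDTH,
    beta_floor: float = 1e-4,
) -> IndelModel:
    """Deterministic-annotation estimate of theta (also the fit's starting point).

    The naive fraction is the fraction of event-free reads, the rescaled
    indel rates are event-count ratios, the age density is a
    kernel-smoothed histogram of per-read mutation loads, and the length
    distributions are smoothed event-length histograms.
    """
    if not annotations:
        raise ValueError("need at least one annotation")
    n = len(annotations)
    f = sum(1 for a in annotations if not a.events) / n
    n_point = sum(a.n_point for a in annotations)
    n_del = sum(a.n_del for a in annotations)
    n_ins = sum(a.n_ins for a in annotations)
    beta_del = max(n_del / max(n_point, 1), beta_floor)
    beta_ins = max(n_ins / max(n_point, 1), beta_floor)
    n_bins = int(round(1.0 / bin_width))
    grid = (np.arange(n_bins) + 0.5) * bin_width
    exp_mu = np.array([a.shm_rate for a in annotations if a.events])
    if len(exp_mu):
        sig = np.sqrt(np.maximum(exp_mu * (1 - exp_mu), 1e-4) / 300.0) + 2 * bin_width
        dens = _smoothed_histogram(exp_mu, sig, grid)
    else:
        dens = np.exp(-grid / 0.05)
        dens /= dens.sum() * bin_width
    del_lengths = [e.length for a in annotations for e in a.events if e.kind == "del"]
    ins_lengths = [
        min(e.length, theta_max) for a in annotations for e in a.events if e.kind == "ins"
    ]
    del_lengths = [min(ell, theta_max) for ell in del_lengths]
    return IndelModel(
        prior=MuPrior(f=min(f, 0.999), density=dens, bin_width=bin_width),
        beta_del=beta_del,
        beta_ins=beta_ins,
        len_del=_smoothed_lengths(del_lengths, theta_max),
        len_ins=_smoothed_lengths(ins_lengths, theta_max),
    )


#: alias used when reporting the deterministic baseline next to the fit
deterministic_estimate = initial_model_from_annotations


# ---------------------------------------------------------------------------
# the full fit
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Outcome of a maximum-likelihood fit."""

    model: IndelModel
    trajectory: pd.DataFrame
    converged: bool
    n_iter: int
    init_model: IndelModel
    posteriors: list[SequencePosterior] = field(default_factory=list, repr=False)


def _posteriors_for_iteration(
    workspaces: list[_SeqWorkspace],
    batch: _Batch,
    model: IndelModel,
    config: OptimizerConfig,
) -> list[SequencePosterior]:
    prior = model.prior
    if config.posterior_mode == "grid":
        node_sets = [prior.centers for _ in workspaces]
    else:
        node_sets = [
            place_nodes(ws.center, ws.spread, ws.n_nodes, prior) for ws in workspaces
        ]
    seq_idx = np.concatenate(
        [np.full(len(nodes), i, dtype=np.int64) for i, nodes in enumerate(node_sets)]
    )
    mus = np.concatenate(node_sets)
    lls = batch.evaluate(
        seq_idx, mus, model.beta_del, model.beta_ins,
        model.len_del.probs, model.len_ins.probs,
    )
    posteriors = []
    pos = 0
    for ws, nodes in zip(workspaces, node_sets):
        ll = lls[pos : pos + len(nodes)]
        pos += len(nodes)
        ll0 = 0.0 if ws.exact0 else -np.inf
        posteriors.append(posterior_from_loglik(nodes, ll, ll0, prior))
    return posteriors


def fit(
    reads: list[NucleotideSequence],
    templates: TemplateSet,
    init: IndelModel | None = None,
    config: OptimizerConfig | None = None,
    penalties: PenaltySet = DEFAULT_PENALTIES,
    pruning: PruningConfig = PruningConfig(),
    theta_max: int = 30,
    bin_width: float = DEFAULT_MU_BIN_WIDTH,
    freeze_phi: bool = False,
    verbose: bool = False,
) -> FitResult:
    """EM + projected momentum gradient ascent on a repertoire.

    Per iteration: age posteriors for every read (nodes + interpolation),
    closed-form prior update, one Monte-Carlo age sample per read, a
    finite-difference gradient of the conditional log-likelihood and a
    projected momentum step on ``phi``.  Template choice and pruning masks
    are fixed once, from the deterministic annotation and an unpruned
    forward/backward pass under the initial model.
    """
    if not reads:
        raise ValueError("no reads to fit")
    config = config or OptimizerConfig()
    rng = np.random.default_rng(config.seed)
    annotations = annotate_repertoire(reads, templates, penalties)
    if init is None:
        init = initial_model_from_annotations(annotations, theta_max, bin_width)
    if init.theta_max != theta_max:
        theta_max = init.theta_max
    workspaces, batch = build_batch(
        reads, templates, init, annotations=annotations, penalties=penalties,
        pruning=pruning,
    )
    for ws in workspaces:
        ws.n_nodes = config.nodes_low if ws.annotation.n_point < 5 else config.nodes_high
    model = init
    phi = init.phi
    phi_prev = phi.copy()
    rows = []
    lls: list[float] = []
    converged = False
    posteriors: list[SequencePosterior] = []
    t_done = 0
    mu_floor = 0.01
    refresh_at = max(2, config.T // 2) if pruning.refresh else None
    for t in range(1, config.T + 1):
        if t == refresh_at:
            # optional mid-fit mask refresh: parameters may have drifted from
            # the initial guess the pruning was computed under
            new_ws, batch = build_batch(
                reads, templates, model, annotations=annotations,
                penalties=penalties, pruning=pruning,
            )
            for ws_new, ws_old in zip(new_ws, workspaces):
                ws_new.center = ws_old.center
                ws_new.spread = ws_old.spread
                ws_new.n_nodes = ws_old.n_nodes
            workspaces = new_ws
        if t > 1:
            batch.refresh_scales(
                model, np.array([max(ws.center, mu_floor) for ws in workspaces])
            )
        posteriors = _posteriors_for_iteration(workspaces, batch, model, config)
        total_ll = float(sum(p.marginal_loglik for p in posteriors))
        new_prior = em_update_prior(posteriors, previous=model.prior)
        model = replace(model, prior=new_prior)
        if not freeze_phi:
            samples = draw_mu_samples(posteriors, config, rng)
            grad = numerical_gradient(phi, samples, batch, config.epsilon)
            # length-probability gradients behave like counts/P and diverge as a
            # component approaches zero; cap them so a rarely supported length
            # rises smoothly to its equilibrium instead of being launched far
            # past it by momentum
            c = config.gradient_clip
            grad[2:] = np.clip(grad[2:], -c, c)
            phi_new = momentum_step(phi, phi_prev, grad, t, config, theta_max)
            phi_prev, phi = phi, phi_new
            model = model.with_phi(phi)
        for ws, p in zip(workspaces, posteriors):
            if p.f_s < 1.0:
                ws.center, ws.spread = p.map_mu, p.spread
        rows.append(
            {
                "iteration": t,
                "loglik": total_ll,
                "f": model.prior.f,
                "beta_del": model.beta_del,
                "beta_ins": model.beta_ins,
            }
        )
        lls.append(total_ll)
        t_done = t
        if verbose:
            logger.info(
                "iter %d loglik %.3f f %.4f bdel %.4f bins %.4f",
                t, total_ll, model.prior.f, model.beta_del, model.beta_ins,
            )
        w = config.convergence_window
        if len(lls) > w:
            rel = abs(lls[-1] - lls[-1 - w]) / max(abs(lls[-1 - w]), 1.0)
            if rel < config.convergence_tol:
                converged = True
                break
    return FitResult(
        model=model,
        trajectory=pd.DataFrame(rows),
        converged=converged,
        n_iter=t_done,
        init_model=init,
        posteriors=posteriors,
    )
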