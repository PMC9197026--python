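"""Sum-over-alignments likelihood of a read given a germline template.

Instead of keeping only the best-scoring alignment, the forward recursion
accumulates the probability of *every* global alignment scenario between
read ``s`` and template ``t``:

    S(s_0:i, t_0:j) = S(s_0:i-1, t_0:j-1) * M(s_i, t_j)
                    + sum_l S(s_0:i, t_0:j-l) * Gamma_del(l)
                    + sum_l S(s_0:i-l, t_0:j) * Gamma_ins(l)

where deletions consume template bases (a gap in the read) and insertions
consume read bases (a gap in the template, paying the ``(1/4)**l`` factor
for the observed non-templated bases).  Event lengths are capped at the
model's ``theta_max``; consecutive indel events are distinct scenarios and
are included in the sum — this is what lets the model disentangle one
long indel from several abutting shorter ones.

Numerics: the recursions run in linear space with an adaptive per-row
rescaling (one scale constant per read position), which is equivalent to
log-space accumulation but much cheaper; results are returned as log or
linear probabilities and a log-sum-exp reference path guards the rare
case where the rescaled recursion overflows.

Pruning: the posterior probability that the true alignment passes through
cell ``(i, j)`` is ``Shat_ij = S(s_1:i, t_1:j) * S(s_i+1:, t_j+1:) / S(s, t)``.
Cells with ``Shat_ij`` below a threshold (default 1e-5) are frozen out of
all subsequent evaluations of the same read, reducing the cost per
evaluation from ``L_s * L_t * (2*theta+1)`` to roughly ``L_s``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .annotate import DEFAULT_PENALTIES, PenaltySet, annotate, encode
from .core import IndelModel, NucleotideSequence, TemplateSet, _check_rate


class DegenerateAlignmentError(ValueError):
    """Raised when a read has zero likelihood under every allowed scenario."""


class PruningTooAggressiveError(ValueError):
    """Raised when a pruning mask disconnects the start from the end cell."""


@dataclass(frozen=True)
class PruningConfig:
    """Pruning threshold on the alignment passage posterior."""

    threshold: float = 1e-5
    refresh: bool = False  # recompute the mask when parameters drift (off by default)

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold < 1.0:
            raise ValueError("pruning threshold must lie in [0, 1)")


# ---------------------------------------------------------------------------
# dense kernels (full matrices; used once per read to build the pruning mask)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _dense_forward_scaled(eq, w_match, w_mis, gdel, gins):  # pragma: no cover
    """Log forward matrix, (L_s+1) x (L_t+1), adaptive per-row rescaling.

    Returns ``(matrix, clamped)``; ``clamped`` signals that cross-row
    scale factors left the representable range (conceivable only at
    absurdly small event weights), in which case the caller must redo the
    computation with the exact log-sum-exp kernel.
    """
    Ls, Lt = eq.shape
    theta = gdel.shape[0]
    V = np.zeros((Ls + 1, Lt + 1))
    C = np.zeros(Ls + 1)
    rho = np.ones(Ls + 1)
    frow = np.ones(theta + 1)
    clamped = False
    V[0, 0] = 1.0
    for j in range(1, Lt + 1):
        acc = 0.0
        lmax = theta if theta < j else j
        for l in range(1, lmax + 1):
            acc += V[0, j - l] * gdel[l - 1]
        V[0, j] = acc
    for i in range(1, Ls + 1):
        m = 0.0
        for j in range(Lt + 1):
            if V[i - 1, j] > m:
                m = V[i - 1, j]
        if m <= 0.0:
            m = 1.0
        C[i] = C[i - 1] + np.log(m)
        rho[i] = 1.0 / m
        frow[0] = 1.0
        for l in range(1, theta + 1):
            k = i - l + 1
            f = frow[l - 1] * (rho[k] if k >= 1 else 1.0)
            if f > 1e280:
                f = 1e280
                clamped = True
            frow[l] = f
        acc = 0.0
        lmax = theta if theta < i else i
        for l in range(1, lmax + 1):
            acc += V[i - l, 0] * frow[l] * gins[l - 1]
        V[i, 0] = acc
        for j in range(1, Lt + 1):
            wm = w_match if eq[i - 1, j - 1] else w_mis
            acc = V[i - 1, j - 1] * rho[i] * wm
            lmax = theta if theta < j else j
            for l in range(1, lmax + 1):
                acc += V[i, j - l] * gdel[l - 1]
            lmax = theta if theta < i else i
            for l in range(1, lmax + 1):
                acc += V[i - l, j] * frow[l] * gins[l - 1]
            V[i, j] = acc
    out = np.empty((Ls + 1, Lt + 1))
    for i in range(Ls + 1):
        for j in range(Lt + 1):
            v = V[i, j]
            out[i, j] = np.log(v) + C[i] if v > 0.0 else -np.inf
    return out, clamped


@njit(cache=True)
def _dense_forward_lse(eq, lw_match, lw_mis, lgdel, lgins):  # pragma: no cover
    """Exact log-space dense forward matrix (slow reference path)."""
    Ls, Lt = eq.shape
    theta = lgdel.shape[0]
    L = np.full((Ls + 1, Lt + 1), -np.inf)
    L[0, 0] = 0.0
    for i in range(Ls + 1):
        for j in range(Lt + 1):
            if i == 0 and j == 0:
                continue
            m = -np.inf
            acc = 0.0
            if i > 0 and j > 0:
                wm = lw_match if eq[i - 1, j - 1] else lw_mis
                t = L[i - 1, j - 1] + wm
                if t > -np.inf:
                    m = t
                    acc = 1.0
            lmax = theta if theta < j else j
            for l in range(1, lmax + 1):
                t = L[i, j - l] + lgdel[l - 1]
                if t == -np.inf:
                    continue
                if t <= m:
                    acc += np.exp(t - m)
                else:
                    acc = acc * np.exp(m - t) + 1.0 if m > -np.inf else 1.0
                    m = t
            lmax = theta if theta < i else i
            for l in range(1, lmax + 1):
                t = L[i - l, j] + lgins[l - 1]
                if t == -np.inf:
                    continue
                if t <= m:
                    acc += np.exp(t - m)
                else:
                    acc = acc * np.exp(m - t) + 1.0 if m > -np.inf else 1.0
                    m = t
            L[i, j] = m + np.log(acc) if m > -np.inf else -np.inf
    return L


def _dense_forward_log(eq, w_match, w_mis, gdel, gins):
    out, clamped = _dense_forward_scaled(eq, w_match, w_mis, gdel, gins)
    if clamped:
        with np.errstate(divide="ignore"):
            out = _dense_forward_lse(
                eq, np.log(w_match), np.log(w_mis), np.log(gdel), np.log(gins)
            )
    return out


@njit(cache=True)
def _build_edges(mask, eq, theta):  # pragma: no cover
    """CSR edge lists over the admissible cells of a pruning mask.

    Cells are enumerated in row-major order; edge types encode the event:
    0 match, 1 mismatch, 2+(l-1) deletion of length l, 2+theta+(l-1)
    insertion of length l.  ``edr`` is the row (read-index) offset of the
    edge source, needed by the rescaled evaluation kernel.
    """
    Ls1, Lt1 = mask.shape
    cellindex = np.full((Ls1, Lt1), -1, np.int32)
    n = 0
    for i in range(Ls1):
        for j in range(Lt1):
            if mask[i, j]:
                cellindex[i, j] = n
                n += 1
    row_ptr = np.zeros(Ls1 + 1, np.int64)
    for i in range(Ls1):
        cnt = 0
        for j in range(Lt1):
            if mask[i, j]:
                cnt += 1
        row_ptr[i + 1] = row_ptr[i] + cnt
    ecount = np.zeros(n + 1, np.int64)
    for i in range(Ls1):
        for j in range(Lt1):
            c = cellindex[i, j]
            if c < 0:
                continue
            cnt = 0
            if i > 0 and j > 0 and cellindex[i - 1, j - 1] >= 0:
                cnt += 1
            lmax = theta if theta < j else j
            for l in range(1, lmax + 1):
                if cellindex[i, j - l] >= 0:
                    cnt += 1
            lmax = theta if theta < i else i
            for l in range(1, lmax + 1):
                if cellindex[i - l, j] >= 0:
                    cnt += 1
            ecount[c + 1] = cnt
    eptr = np.cumsum(ecount)
    ne = eptr[n]
    esrc = np.empty(ne, np.int32)
    etype = np.empty(ne, np.int16)
    edr = np.empty(ne, np.int16)
    edst = np.empty(ne, np.int32)  # destination row (read index) of each edge
    for i in range(Ls1):
        for j in range(Lt1):
            c = cellindex[i, j]
            if c < 0:
                continue
            p = eptr[c]
            if i > 0 and j > 0 and cellindex[i - 1, j - 1] >= 0:
                esrc[p] = cellindex[i - 1, j - 1]
                etype[p] = 0 if eq[i - 1, j - 1] else 1
                edr[p] = 1
                edst[p] = i
                p += 1
            lmax = theta if theta < j else j
            for l in range(1, lmax + 1):
                src = cellindex[i, j - l]
                if src >= 0:
                    esrc[p] = src
                    etype[p] = 2 + (l - 1)
                    edr[p] = 0
                    edst[p] = i
                    p += 1
            lmax = theta if theta < i else i
            for l in range(1, lmax + 1):
                src = cellindex[i - l, j]
                if src >= 0:
                    esrc[p] = src
                    etype[p] = 2 + theta + (l - 1)
                    edr[p] = l
                    edst[p] = i
                    p += 1
    return row_ptr, eptr, esrc, etype, edr, edst


@njit(cache=True)
def _masked_eval_scaled(row_ptr, eptr, esrc, etype, edr, w, theta):  # pragma: no cover
    """Masked forward log-likelihood; linear space with per-row rescaling.

    Returns NaN if the cross-row scale factors leave the representable
    range (absurdly small event weights); callers then redo the
    evaluation with the exact log-sum-exp kernel.
    """
    nrows = row_ptr.shape[0] - 1
    ncells = row_ptr[nrows]
    val = np.zeros(ncells)
    rho = np.ones(nrows)
    frow = np.ones(theta + 1)
    clog = 0.0
    val[0] = 1.0  # cell (0, 0)
    for i in range(nrows):
        if i > 0:
            m = 0.0
            for c in range(row_ptr[i - 1], row_ptr[i]):
                if val[c] > m:
                    m = val[c]
            if m <= 0.0:
                m = 1.0
            clog += np.log(m)
            rho[i] = 1.0 / m
        frow[0] = 1.0
        for l in range(1, theta + 1):
            k = i - l + 1
            f = frow[l - 1] * (rho[k] if k >= 1 else 1.0)
            if f > 1e280:
                return np.nan
            frow[l] = f
        for c in range(row_ptr[i], row_ptr[i + 1]):
            if c == 0:
                continue
            acc = 0.0
            for e in range(eptr[c], eptr[c + 1]):
                acc += val[esrc[e]] * w[etype[e]] * frow[edr[e]]
            val[c] = acc
    v = val[ncells - 1]
    if v > 0.0:
        return np.log(v) + clog
    return -np.inf


@njit(cache=True)
def _masked_eval_lse(row_ptr, eptr, esrc, etype, edr, lw):  # pragma: no cover
    """Masked forward log-likelihood; streaming log-sum-exp (reference path)."""
    nrows = row_ptr.shape[0] - 1
    ncells = row_ptr[nrows]
    lval = np.full(ncells, -np.inf)
    lval[0] = 0.0
    for c in range(1, ncells):
        m = -np.inf
        acc = 0.0
        for e in range(eptr[c], eptr[c + 1]):
            lv = lval[esrc[e]]
            if lv == -np.inf:
                continue
            t = lv + lw[etype[e]]
            if t == -np.inf:
                continue
            if t <= m:
                acc += np.exp(t - m)
            else:
                if m == -np.inf:
                    acc = 1.0
                else:
                    acc = acc * np.exp(m - t) + 1.0
                m = t
        lval[c] = m + np.log(acc) if m > -np.inf else -np.inf
    return lval[ncells - 1]


@njit(cache=True)
def _fill_weights(w, mu, beta_del, beta_ins, pdel, pins, theta):  # pragma: no cover
    pre = 1.0 - mu * (beta_del + beta_ins)
    w[0] = pre * (1.0 - mu)
    w[1] = pre * mu
    f4 = 1.0
    for l in range(1, theta + 1):
        f4 *= 0.25
        w[2 + l - 1] = mu * beta_del * pdel[l - 1]
        w[2 + theta + l - 1] = mu * beta_ins * pins[l - 1] * f4


@njit(cache=True)
def _masked_eval_scales(
    row_ptr, eptr, esrc, etype, edr, w, theta, c_out
):  # pragma: no cover
    """As :func:`_masked_eval_scaled`, but also records the per-row log scales."""
    nrows = row_ptr.shape[0] - 1
    ncells = row_ptr[nrows]
    val = np.zeros(ncells)
    rho = np.ones(nrows)
    frow = np.ones(theta + 1)
    clog = 0.0
    val[0] = 1.0
    for i in range(nrows):
        if i > 0:
            m = 0.0
            for c in range(row_ptr[i - 1], row_ptr[i]):
                if val[c] > m:
                    m = val[c]
            if m <= 0.0:
                m = 1.0
            clog += np.log(m)
            rho[i] = 1.0 / m
        c_out[i] = clog
        frow[0] = 1.0
        for l in range(1, theta + 1):
            k = i - l + 1
            f = frow[l - 1] * (rho[k] if k >= 1 else 1.0)
            if f > 1e280:
                return np.nan
            frow[l] = f
        for c in range(row_ptr[i], row_ptr[i + 1]):
            if c == 0:
                continue
            acc = 0.0
            for e in range(eptr[c], eptr[c + 1]):
                acc += val[esrc[e]] * w[etype[e]] * frow[edr[e]]
            val[c] = acc
    v = val[ncells - 1]
    if v > 0.0:
        return np.log(v) + clog
    return -np.inf


@njit(cache=True)
def _batch_scales(
    mu_ref,
    beta_del,
    beta_ins,
    pdel,
    pins,
    rp_ptr,
    row_ptr,
    ep_ptr,
    eptr_rel,
    edge_base,
    esrc,
    etype,
    edr,
    edst,
    c_ptr,
    c_all,
    cfin,
    ffac,
):  # pragma: no cover
    """Per-sequence row scales at reference ages, and per-edge scale factors."""
    theta = pdel.shape[0]
    w = np.empty(2 + 2 * theta)
    n_seq = mu_ref.shape[0]
    for s in range(n_seq):
        _fill_weights(w, mu_ref[s], beta_del, beta_ins, pdel, pins, theta)
        rp = row_ptr[rp_ptr[s] : rp_ptr[s + 1]]
        ep = eptr_rel[ep_ptr[s] : ep_ptr[s + 1]]
        e0 = edge_base[s]
        e1 = edge_base[s + 1]
        C = c_all[c_ptr[s] : c_ptr[s + 1]]
        ret = _masked_eval_scales(
            rp, ep, esrc[e0:e1], etype[e0:e1], edr[e0:e1], w, theta, C
        )
        if np.isnan(ret):
            # degenerate reference scales; evaluations for this sequence will
            # underflow and be redone with the exact log-sum-exp kernel
            for k in range(C.shape[0]):
                C[k] = 0.0
            cfin[s] = 0.0
            for e in range(e0, e1):
                ffac[e] = 1.0
            continue
        cfin[s] = C[C.shape[0] - 1]
        for e in range(e0, e1):
            i = edst[e]
            d = C[i - edr[e]] - C[i]
            if d > 690.0:
                d = 690.0
            ffac[e] = np.exp(d)


@njit(cache=True)
def _masked_eval_fixed(row_ptr, eptr, esrc, etype, ffac, w, cfin):  # pragma: no cover
    """Masked forward log-likelihood with precomputed per-edge scale factors."""
    nrows = row_ptr.shape[0] - 1
    ncells = row_ptr[nrows]
    val = np.empty(ncells)
    val[0] = 1.0
    for c in range(1, ncells):
        acc = 0.0
        for e in range(eptr[c], eptr[c + 1]):
            acc += val[esrc[e]] * w[etype[e]] * ffac[e]
        val[c] = acc
    v = val[ncells - 1]
    if v > 0.0 and np.isfinite(v):
        return np.log(v) + cfin
    if v == 0.0:
        return -np.inf
    return np.nan  # overflow; caller falls back to the log-sum-exp path


@njit(cache=True)
def _batch_eval(
    eval_seq,
    eval_mu,
    beta_del,
    beta_ins,
    pdel,
    pins,
    rp_ptr,
    row_ptr,
    ep_ptr,
    eptr_rel,
    edge_base,
    esrc,
    etype,
    edr,
    ffac,
    cfin,
    out,
):  # pragma: no cover
    """Evaluate many (sequence, mu) pairs against shared pruned geometries.

    The fast path uses the fixed per-sequence scales of
    :func:`_batch_scales`; any evaluation that underflows to zero or
    overflows is redone with the exact streaming log-sum-exp kernel.
    """
    theta = pdel.shape[0]
    w = np.empty(2 + 2 * theta)
    lw = np.empty(2 + 2 * theta)
    for n in range(eval_seq.shape[0]):
        s = eval_seq[n]
        _fill_weights(w, eval_mu[n], beta_del, beta_ins, pdel, pins, theta)
        rp = row_ptr[rp_ptr[s] : rp_ptr[s + 1]]
        ep = eptr_rel[ep_ptr[s] : ep_ptr[s + 1]]
        e0 = edge_base[s]
        e1 = edge_base[s + 1]
        ll = _masked_eval_fixed(
            rp, ep, esrc[e0:e1], etype[e0:e1], ffac[e0:e1], w, cfin[s]
        )
        if np.isnan(ll) or ll == np.inf or ll == -np.inf:
            for k in range(2 + 2 * theta):
                lw[k] = np.log(w[k]) if w[k] > 0.0 else -np.inf
            ll = _masked_eval_lse(rp, ep, esrc[e0:e1], etype[e0:e1], edr[e0:e1], lw)
        out[n] = ll


# ---------------------------------------------------------------------------
# weight tables
# ---------------------------------------------------------------------------

def _weights(mu: float, model: IndelModel) -> tuple[float, float, np.ndarray, np.ndarray]:
    _check_rate(mu)
    pre = 1.0 - mu * (model.beta_del + model.beta_ins)
    lengths = np.arange(1, model.theta_max + 1)
    gdel = mu * model.beta_del * model.len_del.probs
    gins = mu * model.beta_ins * model.len_ins.probs * 0.25**lengths
    return pre * (1.0 - mu), pre * mu, gdel, gins


def _eq_matrix(s: NucleotideSequence, t: NucleotideSequence) -> np.ndarray:
    return (encode(s.seq)[:, None] == encode(t.seq)[None, :]).astype(np.uint8)


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def log_forward_matrix(
    s: NucleotideSequence, t: NucleotideSequence, mu: float, model: IndelModel
) -> np.ndarray:
    """Log prefix likelihoods S(s_0:i, t_0:j), shape (L_s+1, L_t+1)."""
    wm, wx, gdel, gins = _weights(mu, model)
    return _dense_forward_log(_eq_matrix(s, t), wm, wx, gdel, gins)


def log_backward_matrix(
    s: NucleotideSequence, t: NucleotideSequence, mu: float, model: IndelModel
) -> np.ndarray:
    """Log suffix likelihoods S(s_i+1:, t_j+1:), shape (L_s+1, L_t+1).

    Computed by running the forward recursion on the reversed sequences,
    then flipping the result; entry (L_s, L_t) is 1 (empty suffix).
    """
    wm, wx, gdel, gins = _weights(mu, model)
    eq_rev = _eq_matrix(s, t)[::-1, ::-1].copy()
    rev = _dense_forward_log(eq_rev, wm, wx, gdel, gins)
    return rev[::-1, ::-1].copy()


def forward_sum(
    s: NucleotideSequence,
    t: NucleotideSequence,
    mu: float,
    model: IndelModel,
    mask: np.ndarray | None = None,
) -> float:
    """Total likelihood S(s, t | mu; phi), summed over all alignment scenarios.

    With a ``mask``, scenarios passing through masked-out cells contribute 0.
    """
    return float(np.exp(log_forward_sum(s, t, mu, model, mask)))


def log_forward_sum(
    s: NucleotideSequence,
    t: NucleotideSequence,
    mu: float,
    model: IndelModel,
    mask: np.ndarray | None = None,
) -> float:
    if mask is None:
        return float(log_forward_matrix(s, t, mu, model)[-1, -1])
    if not mask[0, 0] or not mask[s.L, t.L]:
        raise PruningTooAggressiveError("mask must admit the (0,0) and (L_s,L_t) cells")
    theta = model.theta_max
    row_ptr, eptr, esrc, etype, edr, _ = _build_edges(
        np.ascontiguousarray(mask), _eq_matrix(s, t), theta
    )
    wm, wx, gdel, gins = _weights(mu, model)
    w = np.concatenate(([wm, wx], gdel, gins))
    ll = _masked_eval_scaled(row_ptr, eptr, esrc, etype, edr, w, theta)
    if np.isnan(ll) or ll == np.inf:
        with np.errstate(divide="ignore"):
            lw = np.log(w)
        ll = _masked_eval_lse(row_ptr, eptr, esrc, etype, edr, lw)
    return float(ll)


def backward_sum(
    s: NucleotideSequence, t: NucleotideSequence, mu: float, model: IndelModel
) -> np.ndarray:
    """Linear-space suffix likelihood matrix (see :func:`log_backward_matrix`)."""
    return np.exp(log_backward_matrix(s, t, mu, model))


@dataclass
class PassagePosterior:
    """Posterior probability that the alignment passes through each (i, j) cell."""

    shat: np.ndarray
    log_total: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.log_total):
            raise DegenerateAlignmentError(
                "sequence has zero likelihood under the model (S(s,t) = 0)"
            )


def passage_posterior(
    s: NucleotideSequence, t: NucleotideSequence, mu: float, model: IndelModel
) -> PassagePosterior:
    """Shat_ij = S(s_1:i, t_1:j) * S(s_i+1:, t_j+1:) / S(s, t) for every cell."""
    lf = log_forward_matrix(s, t, mu, model)
    lb = log_backward_matrix(s, t, mu, model)
    log_total = lf[-1, -1]
    if not np.isfinite(log_total):
        raise DegenerateAlignmentError(
            f"read {s.id!r} has zero likelihood against template {t.id!r} at mu={mu}"
        )
    shat = np.exp(np.minimum(lf + lb - log_total, 700.0))
    return PassagePosterior(shat=shat, log_total=float(log_total))


def build_pruning_mask(
    posterior: PassagePosterior, config: PruningConfig = PruningConfig()
) -> np.ndarray:
    """Admit cell (i, j) iff Shat_ij >= threshold."""
    mask = posterior.shat >= config.threshold
    if not mask[0, 0] or not mask[-1, -1]:
        raise PruningTooAggressiveError(
            "pruning mask excludes an endpoint cell; lower the threshold"
        )
    return mask


def select_template(
    s: NucleotideSequence,
    templates: TemplateSet,
    penalties: PenaltySet = DEFAULT_PENALTIES,
) -> str:
    """Id of the template closest to ``s`` under the deterministic NW score.

    The probabilistic likelihood subsequently keeps only this template:
    the repertoire marginal sum over templates is overwhelmingly dominated
    by the best one.
    """
    return annotate(s, templates, penalties).best_template


def sequence_likelihood(
    s: NucleotideSequence,
    t_star: NucleotideSequence,
    theta: IndelModel,
    mu_grid: np.ndarray | None = None,
    mask: np.ndarray | None = None,
) -> float:
    """Marginal likelihood L(s; theta) = f*S(s,t*|0) + (1-f) * int Ptilde(mu) S(s,t*|mu) dmu.

    The integral is a midpoint-rule quadrature over the binned prior; a
    finer uniform ``mu_grid`` may be supplied (the prior density is then
    interpolated onto it and renormalized).
    """
    prior = theta.prior
    if mu_grid is None:
        mu_grid = prior.centers
        dens = prior.density
        h = prior.bin_width
    else:
        mu_grid = np.asarray(mu_grid, dtype=float)
        if len(mu_grid) < 2:
            dens = np.array([1.0 / (mu_grid[0] if mu_grid[0] > 0 else 1.0)])
            h = 1.0  # single-point quadrature: weight collapses to the point mass
            ll = log_forward_sum(s, t_star, float(mu_grid[0]), theta, mask)
            s0 = log_forward_sum(s, t_star, 0.0, theta, mask)
            return float(prior.f * np.exp(s0) + (1 - prior.f) * np.exp(ll))
        h = float(mu_grid[1] - mu_grid[0])
        dens = np.interp(mu_grid, prior.centers, prior.density)
        total = dens.sum() * h
        if total <= 0:
            raise ValueError("prior has no mass on the supplied grid")
        dens = dens / total
    lls = np.array(
        [
            log_forward_sum(s, t_star, float(mu), theta, mask) if d > 0 else -np.inf
            for mu, d in zip(mu_grid, dens)
        ]
    )
    with np.errstate(over="ignore"):
        smooth = float(np.sum(np.exp(lls[dens > 0]) * dens[dens > 0]) * h)
    s0 = np.exp(log_forward_sum(s, t_star, 0.0, theta, mask))
    return float(prior.f * s0 + (1 - prior.f) * smooth)
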