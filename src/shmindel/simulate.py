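"""Synthetic repertoire generation under the SHM-indel model.

Each read is produced by (1) drawing a germline template from the
template prior, (2) drawing a maturation age ``mu`` from the repertoire
prior (a naive fraction ``f`` at exactly ``mu = 0`` plus a smooth density
for experienced cells), and (3) sweeping the template once, position by
position: at each position an independent draw starts a deletion (rate
``mu*beta_del`` per bp), starts an insertion (rate ``mu*beta_ins``),
substitutes the base (rate ``mu*(1 - mu*beta_del - mu*beta_ins)``), or
leaves it untouched.  Event lengths come from the model's length
distributions; inserted bases are uniform over {A, C, G, T}.

The benchmark conditions used throughout the test-bed mimic a realistic
IgG repertoire: 10% naive cells, experienced-cell ages from a shifted
Gamma distribution with mode 0.05, rescaled indel rates
``beta_del = beta_ins = 0.025``, and geometric event lengths of
characteristic scale 15 bp truncated at 30 bp.

Boundary rules (rare at realistic rates): a deletion that would overrun
the 3' template end is truncated there; an indel starting inside an
already-deleted stretch is discarded; point mutations hit only
template-derived positions, at most once.  Ground-truth scenarios record
exactly the events that were applied, so replaying a scenario on its
template reproduces the read byte for byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .core import (
    ALPHABET,
    DEFAULT_MU_BIN_WIDTH,
    DEFAULT_THETA_MAX,
    IndelModel,
    LengthDistribution,
    MuPrior,
    MutationEvent,
    MutationScenario,
    NucleotideSequence,
    TemplateSet,
)

#: benchmark generative parameters (realistic IgG-like repertoire)
BENCHMARK_NAIVE_FRACTION = 0.1
BENCHMARK_BETA = 0.025
BENCHMARK_LENGTH_SCALE = 15.0


@dataclass(frozen=True)
class ShiftedGammaSpec:
    """Shifted Gamma distribution of experienced-cell mutation rates.

    The unshifted Gamma has the given ``mode`` and standard deviation
    ``sd``; samples are shifted down by ``shift`` and negative values are
    rejected, so the resulting density is proportional to
    ``(mu + shift)**(alpha-1) * exp(-beta*(mu + shift))`` on ``mu >= 0``
    and has mode ``mode - shift`` (0.05 for the defaults).
    """

    mode: float = 0.07
    sd: float = 0.04
    shift: float = 0.02

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be positive")
        if self.mode <= 0:
            raise ValueError("mode must be positive")
        if self.shift < 0:
            raise ValueError("shift must be >= 0")

    @property
    def alpha(self) -> float:
        # solve (alpha-1)/beta = mode, sqrt(alpha)/beta = sd  =>
        # sd*x**2 - mode*x - sd = 0 with x = sqrt(alpha)
        x = (self.mode + math.sqrt(self.mode**2 + 4 * self.sd**2)) / (2 * self.sd)
        return x * x

    @property
    def beta(self) -> float:
        return math.sqrt(self.alpha) / self.sd

    def log_density_unnormalized(self, mu: np.ndarray) -> np.ndarray:
        mu = np.asarray(mu, dtype=float)
        out = np.full(mu.shape, -np.inf)
        ok = mu >= 0
        x = mu[ok] + self.shift
        out[ok] = (self.alpha - 1) * np.log(x) - self.beta * x
        return out

    def analytic_mode(self) -> float:
        """Mode of the shifted, negative-rejected density, found numerically."""
        res = optimize.minimize_scalar(
            lambda m: -float(self.log_density_unnormalized(np.array([m]))[0]),
            bounds=(0.0, 1.0),
            method="bounded",
            options={"xatol": 1e-10},
        )
        return float(res.x)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Rejection sampling: Gamma draws shifted down, negatives redrawn."""
        out = np.empty(n)
        filled = 0
        while filled < n:
            draw = rng.gamma(self.alpha, 1.0 / self.beta, size=2 * (n - filled)) - self.shift
            draw = draw[draw >= 0]
            take = min(len(draw), n - filled)
            out[filled : filled + take] = draw[:take]
            filled += take
        return out

    def to_prior(self, f: float, bin_width: float = DEFAULT_MU_BIN_WIDTH) -> MuPrior:
        """Discretize onto the standard mu binning, for use as an IndelModel prior."""
        return MuPrior.from_density_callable(
            f, lambda mu: np.exp(self.log_density_unnormalized(mu)), bin_width
        )


def benchmark_model(
    theta_max: int = DEFAULT_THETA_MAX,
    f: float = BENCHMARK_NAIVE_FRACTION,
    beta_del: float = BENCHMARK_BETA,
    beta_ins: float = BENCHMARK_BETA,
    length_scale: float = BENCHMARK_LENGTH_SCALE,
    gamma: ShiftedGammaSpec = ShiftedGammaSpec(),
    bin_width: float = DEFAULT_MU_BIN_WIDTH,
) -> IndelModel:
    """The standard synthetic-benchmark generative model (see module docstring)."""
    return IndelModel(
        prior=gamma.to_prior(f, bin_width),
        beta_del=beta_del,
        beta_ins=beta_ins,
        len_del=LengthDistribution.geometric(length_scale, theta_max),
        len_ins=LengthDistribution.geometric(length_scale, theta_max),
    )


def random_templates(
    n: int, length: int, seed: int | np.random.Generator = 0, prefix: str = "V"
) -> TemplateSet:
    """Uniform-random germline templates (synthetic stand-ins for V genes)."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    templates = [
        NucleotideSequence(
            id=f"{prefix}{k + 1:02d}", seq="".join(rng.choice(list(ALPHABET), size=length))
        )
        for k in range(n)
    ]
    return TemplateSet(templates)


def sample_mu(
    prior: MuPrior | ShiftedGammaSpec,
    n: int,
    seed: int | np.random.Generator = 0,
    f: float | None = None,
) -> np.ndarray:
    """Draw maturation ages: exactly 0 with probability ``f``, else from the density.

    ``prior`` may be a binned :class:`MuPrior` (its own ``f`` is used) or a
    :class:`ShiftedGammaSpec` together with an explicit naive fraction ``f``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if isinstance(prior, ShiftedGammaSpec):
        if f is None:
            raise ValueError("a naive fraction f is required with a ShiftedGammaSpec")
        naive = rng.random(n) < f
        out = np.zeros(n)
        n_exp = int((~naive).sum())
        if n_exp:
            out[~naive] = prior.sample(n_exp, rng)
        return out
    if f is not None:
        raise ValueError("f is taken from the MuPrior; do not pass it separately")
    naive = rng.random(n) < prior.f
    out = np.zeros(n)
    n_exp = int((~naive).sum())
    if n_exp:
        cdf = np.cumsum(prior.density)
        cdf /= cdf[-1]
        idx = np.searchsorted(cdf, rng.random(n_exp))
        jitter = rng.random(n_exp)
        out[~naive] = (idx + jitter) * prior.bin_width
    return out


def _draw_length(dist: LengthDistribution, rng: np.random.Generator) -> int:
    return int(rng.choice(dist.lengths, p=dist.probs))


def mutate_sequence(
    template: NucleotideSequence,
    mu: float,
    model: IndelModel,
    seed: int | np.random.Generator = 0,
) -> tuple[str, MutationScenario]:
    """Apply one sweep of the per-position mutation process to a template.

    Returns the mutated read and the ground-truth scenario that exactly
    reconstructs it via :meth:`MutationScenario.apply`.
    """
    if not 0.0 <= mu <= 1.0:
        raise ValueError("mu must lie in [0, 1]")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    L = template.L
    p_del = mu * model.beta_del
    p_ins = mu * model.beta_ins
    p_point = (1.0 - p_del - p_ins) * mu
    u = rng.random(L)
    del_starts = np.flatnonzero(u < p_del)
    ins_starts = np.flatnonzero((u >= p_del) & (u < p_del + p_ins))
    point_pos = np.flatnonzero(
        (u >= p_del + p_ins) & (u < p_del + p_ins + p_point)
    )
    events: list[MutationEvent] = []
    deleted = np.zeros(L, dtype=bool)
    # deletions left to right: a start inside an already-deleted stretch is
    # discarded; a deletion overrunning the template end is truncated.
    for j in del_starts:
        j = int(j)
        if deleted[j]:
            continue
        ell = _draw_length(model.len_del, rng)
        end = min(j + ell, L)
        deleted[j:end] = True
        events.append(MutationEvent("del", j, end - j))
    for j in ins_starts:
        j = int(j)
        if deleted[j]:
            continue
        ell = _draw_length(model.len_ins, rng)
        bases = "".join(rng.choice(list(ALPHABET), size=ell))
        events.append(MutationEvent("ins", j, ell, inserted_seq=bases))
    for j in point_pos:
        j = int(j)
        if deleted[j]:
            continue
        old = template.seq[j]
        alternatives = [b for b in ALPHABET if b != old]
        events.append(
            MutationEvent("point", j, 1, new_base=str(rng.choice(alternatives)))
        )
    events.sort(key=lambda e: (e.position, e.kind))
    scenario = MutationScenario(template_id=template.id, mu=float(mu), events=events)
    return scenario.apply(template), scenario


@dataclass
class SyntheticRepertoire:
    """A generated repertoire together with its ground truth."""

    reads: list[NucleotideSequence]
    truth: list[MutationScenario]
    seed: int
    model: IndelModel
    templates: TemplateSet

    def __post_init__(self) -> None:
        if len(self.reads) != len(self.truth):
            raise ValueError("reads and truth must have equal length")

    def __len__(self) -> int:
        return len(self.reads)

    def annotated_truth(self) -> list[tuple[str, MutationScenario]]:
        return [(r.id, sc) for r, sc in zip(self.reads, self.truth)]


def generate_repertoire(
    templates: TemplateSet,
    model: IndelModel,
    n: int,
    seed: int = 0,
    mu_override: np.ndarray | None = None,
) -> SyntheticRepertoire:
    """Generate ``n`` reads: template ~ prior, mu ~ P(mu), then one mutation sweep.

    Deterministic under ``seed``; each read draws from its own RNG stream
    spawned from the master seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n + 1)
    master = np.random.default_rng(children[0])
    t_idx = master.choice(templates.N_t, size=n, p=templates.prior)
    if mu_override is not None:
        mus = np.asarray(mu_override, dtype=float)
        if mus.shape != (n,):
            raise ValueError("mu_override must have one entry per read")
    else:
        mus = sample_mu(model.prior, n, master)
    reads: list[NucleotideSequence] = []
    truth: list[MutationScenario] = []
    child_seeds = children[1:]
    for k in range(n):
        rng_k = np.random.default_rng(child_seeds[k])
        template = templates.templates[int(t_idx[k])]
        read, scenario = mutate_sequence(template, float(mus[k]), model, rng_k)
        reads.append(NucleotideSequence(id=f"read_{k:06d}", seq=read))
        truth.append(scenario)
    return SyntheticRepertoire(
        reads=reads, truth=truth, seed=seed, model=model, templates=templates
    )
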