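"""Domain types and elementary event probabilities of the SHM-indel model.

The generative model: each antibody sequence derives from a germline V
template through somatic hypermutation.  A sequence-specific "maturation
age" ``mu`` (point-mutation rate per base pair) is drawn from a repertoire
prior ``P(mu) = f*delta(mu) + (1-f)*Ptilde(mu)``, where ``f`` is the
fraction of naive (unmutated, ``mu = 0``) cells.  Conditioned on ``mu``,
deletion and insertion events start at per-base-pair rates
``mu*beta_del`` and ``mu*beta_ins``; event lengths are drawn from the
length distributions ``P_del`` / ``P_ins`` supported on ``1..theta_max``;
inserted nucleotides are uniform over {A, C, G, T}.

The elementary probabilities used by both the simulator and the alignment
likelihood are:

* a deletion event of length ``ell``:   ``Gamma_del(ell) = mu*beta_del*P_del(ell)``
* an insertion event of length ``ell`` with given bases:
  ``Gamma_ins(ell) = mu*beta_ins*P_ins(ell)*(1/4)**ell``
* an aligned pair of bases ``(a, b)``:
  ``M(a, b) = (1 - mu*beta_del - mu*beta_ins) * ((1-mu) if a == b else mu)``

Note that the mismatch term carries weight ``mu`` regardless of which of
the three alternative bases is observed; the per-position emission mass is
therefore not exactly 1.  This is a deliberate feature of the model
parameterization (the mismatch penalty ``ln mu`` of the deterministic
aligner follows from it) and is implemented literally.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

ALPHABET = "ACGT"
_ALPHASET = frozenset(ALPHABET)

#: default maximum length (bp) of a single insertion or deletion event
DEFAULT_THETA_MAX = 30

#: bin width of the discretized mu prior on [0, 1]
DEFAULT_MU_BIN_WIDTH = 0.0005


class ModelValidationError(ValueError):
    """Raised when model parameters violate the model's constraints."""


def _check_rate(mu: float) -> None:
    if not 0.0 <= mu <= 1.0:
        raise ValueError(f"mutation rate mu must lie in [0, 1], got {mu}")


@dataclass(frozen=True)
class NucleotideSequence:
    """A named DNA sequence over the strict alphabet {A, C, G, T}."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if len(self.seq) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")
        if not _ALPHASET.issuperset(self.seq):
            bad = sorted(set(self.seq) - _ALPHASET)
            raise ValueError(f"sequence {self.id!r} contains non-ACGT symbols: {bad}")

    @property
    def L(self) -> int:
        return len(self.seq)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class TemplateSet:
    """A set of germline V templates with a prior probability per template."""

    templates: list[NucleotideSequence]
    prior: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.templates:
            raise ValueError("TemplateSet requires at least one template")
        ids = [t.id for t in self.templates]
        if len(set(ids)) != len(ids):
            raise ValueError("template ids must be unique")
        if self.prior is None:
            self.prior = np.full(len(self.templates), 1.0 / len(self.templates))
        else:
            self.prior = np.asarray(self.prior, dtype=float)
            if self.prior.shape != (len(self.templates),):
                raise ValueError("prior length must match number of templates")
            if np.any(self.prior < 0) or abs(self.prior.sum() - 1.0) > 1e-9:
                raise ValueError("template prior must be a probability vector")
        self._by_id = {t.id: t for t in self.templates}

    @property
    def N_t(self) -> int:
        return len(self.templates)

    def __iter__(self):
        return iter(self.templates)

    def __getitem__(self, template_id: str) -> NucleotideSequence:
        return self._by_id[template_id]


@dataclass
class LengthDistribution:
    """Distribution of single-event indel lengths on ``1..theta_max``.

    ``probs[k]`` is the probability of an event of length ``k + 1`` base
    pairs; lengths above ``theta_max`` have probability zero by
    construction.
    """

    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 1 or len(self.probs) < 1:
            raise ModelValidationError("length distribution needs >= 1 entry")
        if np.any(self.probs < 0):
            raise ModelValidationError("length probabilities must be >= 0")
        if abs(self.probs.sum() - 1.0) > 1e-9:
            raise ModelValidationError(
                f"length distribution must sum to 1, got {self.probs.sum()!r}"
            )

    @property
    def theta_max(self) -> int:
        return len(self.probs)

    @property
    def lengths(self) -> np.ndarray:
        return np.arange(1, self.theta_max + 1)

    def pmf(self, ell: int) -> float:
        if ell < 1:
            raise ValueError(f"event length must be >= 1, got {ell}")
        if ell > self.theta_max:
            return 0.0
        return float(self.probs[ell - 1])

    def mean(self) -> float:
        return float(np.dot(self.lengths, self.probs))

    @classmethod
    def geometric(cls, scale: float, theta_max: int = DEFAULT_THETA_MAX) -> "LengthDistribution":
        """Truncated geometric profile ``P(ell) ~ exp(-ell/scale)``, ``ell = 1..theta_max``."""
        if scale <= 0:
            raise ValueError("characteristic scale must be positive")
        w = np.exp(-np.arange(1, theta_max + 1) / scale)
        return cls(w / w.sum())

    @classmethod
    def uniform(cls, theta_max: int = DEFAULT_THETA_MAX) -> "LengthDistribution":
        return cls(np.full(theta_max, 1.0 / theta_max))

    def extended(self, theta_max: int) -> "LengthDistribution":
        """Re-embed on a larger support, padding lengths above the current cutoff with 0."""
        if theta_max < self.theta_max:
            raise ValueError("cannot shrink the support of a length distribution")
        probs = np.zeros(theta_max)
        probs[: self.theta_max] = self.probs
        return LengthDistribution(probs)


@dataclass
class MuPrior:
    """Repertoire-wide prior over maturation age: naive mass + binned density.

    ``density`` holds the smooth part ``Ptilde(mu)`` as a per-unit density
    evaluated at the centers of uniform bins of width ``bin_width`` tiling
    [0, 1]; it integrates to 1 (``density.sum() * bin_width == 1``).
    """

    f: float
    density: np.ndarray
    bin_width: float = DEFAULT_MU_BIN_WIDTH

    def __post_init__(self) -> None:
        if not 0.0 <= self.f <= 1.0:
            raise ModelValidationError(f"naive fraction f must lie in [0, 1], got {self.f}")
        self.density = np.asarray(self.density, dtype=float)
        n_bins = int(round(1.0 / self.bin_width))
        if abs(n_bins * self.bin_width - 1.0) > 1e-9:
            raise ModelValidationError("bin_width must divide the [0, 1] interval evenly")
        if self.density.shape != (n_bins,):
            raise ModelValidationError(
                f"density must have {n_bins} bins for bin_width {self.bin_width}"
            )
        if np.any(self.density < 0):
            raise ModelValidationError("density must be >= 0")
        if abs(self.density.sum() * self.bin_width - 1.0) > 1e-6:
            raise ModelValidationError("density must integrate to 1 within 1e-6")

    @property
    def n_bins(self) -> int:
        return len(self.density)

    @property
    def centers(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) * self.bin_width

    def mean_experienced(self) -> float:
        """Mean of the smooth (experienced-cell) component."""
        return float(np.dot(self.centers, self.density) * self.bin_width)

    @classmethod
    def from_density_callable(
        cls, f: float, pdf, bin_width: float = DEFAULT_MU_BIN_WIDTH
    ) -> "MuPrior":
        n_bins = int(round(1.0 / bin_width))
        centers = (np.arange(n_bins) + 0.5) * bin_width
        dens = np.clip(np.asarray(pdf(centers), dtype=float), 0.0, None)
        total = dens.sum() * bin_width
        if total <= 0:
            raise ModelValidationError("density callable has no mass on [0, 1]")
        return cls(f=f, density=dens / total, bin_width=bin_width)


@dataclass
class IndelModel:
    """Full SHM-indel parameter set ``theta = (P(mu), beta_del, beta_ins, P_del, P_ins)``."""

    prior: MuPrior
    beta_del: float
    beta_ins: float
    len_del: LengthDistribution
    len_ins: LengthDistribution

    def __post_init__(self) -> None:
        if self.beta_del < 0 or self.beta_ins < 0:
            raise ModelValidationError("beta_del and beta_ins must be >= 0")
        if self.len_del.theta_max != self.len_ins.theta_max:
            raise ModelValidationError(
                "deletion and insertion length distributions must share theta_max"
            )
        # M(.) of the match probability must stay in [0, 1] for any mu in [0, 1];
        # the binding case is mu = 1.
        if self.beta_del + self.beta_ins > 1.0:
            raise ModelValidationError(
                "beta_del + beta_ins must be <= 1 so that the per-position "
                "match probability stays in [0, 1] for all mu"
            )

    @property
    def theta_max(self) -> int:
        return self.len_del.theta_max

    @property
    def phi(self) -> np.ndarray:
        """Indel parameters as a flat vector (beta_del, beta_ins, P_del, P_ins)."""
        return np.concatenate(
            ([self.beta_del, self.beta_ins], self.len_del.probs, self.len_ins.probs)
        )

    def with_phi(self, phi: np.ndarray) -> "IndelModel":
        th = self.theta_max
        if len(phi) != 2 + 2 * th:
            raise ValueError("phi vector has the wrong length")
        return replace(
            self,
            beta_del=float(phi[0]),
            beta_ins=float(phi[1]),
            len_del=LengthDistribution(phi[2 : 2 + th]),
            len_ins=LengthDistribution(phi[2 + th :]),
        )


@dataclass(frozen=True)
class MutationEvent:
    """One elementary mutation event in template coordinates (0-based, half-open)."""

    kind: str  # "point" | "del" | "ins"
    position: int
    length: int = 1
    inserted_seq: str = ""
    new_base: str = ""  # for point events: the substituted base

    def __post_init__(self) -> None:
        if self.kind not in ("point", "del", "ins"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.position < 0:
            raise ValueError("event position must be >= 0")
        if self.kind == "ins":
            if len(self.inserted_seq) != self.length:
                raise ValueError("inserted_seq length must equal event length")
        else:
            if self.inserted_seq:
                raise ValueError("only insertions carry inserted bases")
        if self.kind == "point" and self.length != 1:
            raise ValueError("point events have length 1")
        if self.length < 1:
            raise ValueError("event length must be >= 1")


@dataclass
class MutationScenario:
    """One concrete generation history: template, age, and ordered events."""

    template_id: str
    mu: float
    events: list[MutationEvent] = field(default_factory=list)

    def count(self, kind: str) -> int:
        return sum(1 for e in self.events if e.kind == kind)

    @property
    def n_point(self) -> int:
        return self.count("point")

    @property
    def n_del(self) -> int:
        return self.count("del")

    @property
    def n_ins(self) -> int:
        return self.count("ins")

    def apply(self, template: NucleotideSequence) -> str:
        """Reconstruct the read produced by this scenario from its template.

        Deletions remove template slots, point events substitute a slot,
        insertions place bases immediately before a template slot
        (position ``L_t`` appends at the 3' end).  The result is
        independent of event order as long as at most one substitution or
        deletion touches each slot, which the simulator guarantees.
        """
        L = template.L
        slots = list(template.seq)
        ins_buf = [""] * (L + 1)
        for e in self.events:
            if e.kind == "del":
                if e.position + e.length > L:
                    raise ValueError("deletion overruns template end")
                for j in range(e.position, e.position + e.length):
                    slots[j] = ""
            elif e.kind == "point":
                if e.position >= L:
                    raise ValueError("point event beyond template end")
                slots[e.position] = e.new_base
            else:  # ins
                if e.position > L:
                    raise ValueError("insertion beyond template end")
                ins_buf[e.position] += e.inserted_seq
        parts = []
        for j in range(L):
            parts.append(ins_buf[j])
            parts.append(slots[j])
        parts.append(ins_buf[L])
        return "".join(parts)


# ---------------------------------------------------------------------------
# elementary event probabilities
# ---------------------------------------------------------------------------

def gamma_del(ell: int, mu: float, model: IndelModel) -> float:
    """Probability of a deletion event of length ``ell`` at rate ``mu``."""
    if ell < 1:
        raise ValueError(f"event length must be >= 1, got {ell}")
    _check_rate(mu)
    return mu * model.beta_del * model.len_del.pmf(ell)


def gamma_ins(ell: int, mu: float, model: IndelModel) -> float:
    """Probability of inserting ``ell`` specific bases at rate ``mu``.

    The ``(1/4)**ell`` factor is the probability of the particular
    inserted nucleotides under the uniform-insertion assumption.
    """
    if ell < 1:
        raise ValueError(f"event length must be >= 1, got {ell}")
    _check_rate(mu)
    return mu * model.beta_ins * model.len_ins.pmf(ell) * 0.25**ell


def match_prob(a: str, b: str, mu: float, model: IndelModel) -> float:
    """Probability of observing read base ``a`` aligned to template base ``b``."""
    if a not in _ALPHASET or b not in _ALPHASET:
        raise ValueError(f"bases must be one of {ALPHABET}, got {a!r}, {b!r}")
    _check_rate(mu)
    p = (1.0 - mu * model.beta_del - mu * model.beta_ins) * ((1.0 - mu) if a == b else mu)
    if not 0.0 <= p <= 1.0:
        raise ModelValidationError(f"match probability {p} outside [0, 1]")
    return p
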