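"""Descriptive indel statistics of an annotated repertoire.

All operations accept a list of :class:`AnnotatedRead` — a read, the
germline template it derives from, and an event list in template-local
0-based coordinates.  Annotations can come from ground-truth simulation
scenarios or from the deterministic aligner, which makes the two directly
comparable (the comparison is how annotation artifacts such as the
merging of nearby deletions are exposed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .annotate import DeterministicAnnotation
from .core import ALPHABET, MutationScenario, NucleotideSequence, TemplateSet
from .simulate import SyntheticRepertoire


@dataclass
class AnnotatedRead:
    read: NucleotideSequence
    template: NucleotideSequence
    scenario: MutationScenario

    @property
    def n_deleted(self) -> int:
        return sum(e.length for e in self.scenario.events if e.kind == "del")

    @property
    def aligned_bp(self) -> int:
        """Template base pairs covered by the alignment (not deleted)."""
        return self.template.L - self.n_deleted

    @property
    def shm_rate(self) -> float:
        n = self.aligned_bp
        return self.scenario.n_point / n if n else 0.0


def from_truth(rep: SyntheticRepertoire) -> list[AnnotatedRead]:
    return [
        AnnotatedRead(read=r, template=rep.templates[sc.template_id], scenario=sc)
        for r, sc in zip(rep.reads, rep.truth)
    ]


def from_deterministic(
    annotations: list[DeterministicAnnotation],
    reads: list[NucleotideSequence],
    templates: TemplateSet,
) -> list[AnnotatedRead]:
    return [
        AnnotatedRead(read=r, template=templates[a.best_template], scenario=a.to_scenario())
        for a, r in zip(annotations, reads)
    ]


def per_seq_table(annots: list[AnnotatedRead]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "read_id": [a.read.id for a in annots],
            "template_id": [a.template.id for a in annots],
            "n_point": [a.scenario.n_point for a in annots],
            "n_del_events": [a.scenario.n_del for a in annots],
            "n_ins_events": [a.scenario.n_ins for a in annots],
            "shm_rate": [a.shm_rate for a in annots],
        }
    )


def indel_count_distribution(annots: list[AnnotatedRead]) -> tuple[pd.DataFrame, dict]:
    """Fraction of reads with exactly n indels, plus maximum-likelihood Poisson means.

    Returned per event type ("del", "ins") and cumulated ("all"); the
    Poisson mean (the MLE is the sample mean) gives the closest Poisson
    trend for comparison — the generative model is super-Poissonian
    because the event rate varies across sequences.
    """
    if not annots:
        raise ValueError("no annotations")
    counts = {
        "del": np.array([a.scenario.n_del for a in annots]),
        "ins": np.array([a.scenario.n_ins for a in annots]),
        "all": np.array([a.scenario.n_del + a.scenario.n_ins for a in annots]),
    }
    n_max = max(int(c.max()) for c in counts.values())
    rows = []
    for n in range(n_max + 1):
        rows.append(
            {"n": n, **{k: float(np.mean(c == n)) for k, c in counts.items()}}
        )
    means = {k: float(c.mean()) for k, c in counts.items()}
    return pd.DataFrame(rows), means


def shm_conditional_on_indels(annots: list[AnnotatedRead]) -> pd.DataFrame:
    """Mean SHM fraction conditioned on hosting exactly n indel events."""
    df = per_seq_table(annots)
    df["n_indels"] = df["n_del_events"] + df["n_ins_events"]
    out = (
        df.groupby("n_indels")["shm_rate"]
        .agg(["mean", "std", "count"])
        .reset_index()
        .rename(columns={"mean": "mean_shm", "std": "sd_shm"})
    )
    return out


def _event_read_positions(a: AnnotatedRead) -> dict[int, int]:
    """Read-coordinate start of each insertion event, keyed by event index.

    Walks the template slots the same way scenario application does.
    """
    L = a.template.L
    slot_len = np.ones(L, dtype=int)
    ins_at: dict[int, list[int]] = {}
    for k, e in enumerate(a.scenario.events):
        if e.kind == "del":
            slot_len[e.position : e.position + e.length] = 0
        elif e.kind == "ins":
            ins_at.setdefault(e.position, []).append(k)
    # prefix read length before template slot j
    out: dict[int, int] = {}
    pos = 0
    for j in range(L + 1):
        for k in ins_at.get(j, []):
            out[k] = pos
            pos += a.scenario.events[k].length
        if j < L:
            pos += slot_len[j]
    return out


def _overlap(a: str, b: str) -> float:
    return sum(x == y for x, y in zip(a, b)) / len(a)


def insertion_flank_overlap(
    annots: list[AnnotatedRead],
    randomize: bool = False,
    rng: np.random.Generator | int = 0,
) -> pd.DataFrame:
    """Overlap of inserted segments with their same-length read flanks.

    For each insertion the inserted bases are compared with the
    immediately 5' and 3' stretches of the same length along the read;
    the larger overlap fraction is reported with its side.  With
    ``randomize`` the inserted bases are replaced by uniform random ones
    (the null of the duplication signature).  Events whose flanks are
    truncated by the read boundary are skipped and counted.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    rows = []
    n_skipped = 0
    for a in annots:
        read_pos = _event_read_positions(a)
        for k, e in enumerate(a.scenario.events):
            if e.kind != "ins":
                continue
            start = read_pos[k]
            ell = e.length
            if start < ell or start + 2 * ell > len(a.read.seq):
                n_skipped += 1
                continue
            ins = e.inserted_seq
            if randomize:
                ins = "".join(rng.choice(list(ALPHABET), size=ell))
            five = a.read.seq[start - ell : start]
            three = a.read.seq[start + ell : start + 2 * ell]
            o5, o3 = _overlap(ins, five), _overlap(ins, three)
            rows.append(
                {
                    "read_id": a.read.id,
                    "length": ell,
                    "overlap": max(o5, o3),
                    "side": "5p" if o5 >= o3 else "3p",
                    "overlap_5p": o5,
                    "overlap_3p": o3,
                }
            )
    df = pd.DataFrame(rows, columns=["read_id", "length", "overlap", "side", "overlap_5p", "overlap_3p"])
    df.attrs["n_skipped"] = n_skipped
    return df


def deletion_flank_overlap(
    annots: list[AnnotatedRead],
    randomize: bool = False,
    rng: np.random.Generator | int = 0,
) -> pd.DataFrame:
    """Overlap of deleted segments with their same-length template flanks."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    rows = []
    n_skipped = 0
    for a in annots:
        tseq = a.template.seq
        for e in a.scenario.events:
            if e.kind != "del":
                continue
            j, ell = e.position, e.length
            if j < ell or j + 2 * ell > len(tseq):
                n_skipped += 1
                continue
            seg = tseq[j : j + ell]
            if randomize:
                seg = "".join(rng.choice(list(ALPHABET), size=ell))
            o5 = _overlap(seg, tseq[j - ell : j])
            o3 = _overlap(seg, tseq[j + ell : j + 2 * ell])
            rows.append(
                {
                    "read_id": a.read.id,
                    "length": ell,
                    "overlap": max(o5, o3),
                    "side": "5p" if o5 >= o3 else "3p",
                    "overlap_5p": o5,
                    "overlap_3p": o3,
                }
            )
    df = pd.DataFrame(rows, columns=["read_id", "length", "overlap", "side", "overlap_5p", "overlap_3p"])
    df.attrs["n_skipped"] = n_skipped
    return df


def deletion_pair_distances(annots: list[AnnotatedRead]) -> np.ndarray:
    """Distances (bp in between) for reads with exactly two deletions, no insertions.

    Template coordinates, half-open: a deletion ending at position 10
    (exclusive) followed by one starting at 15 is at distance 5.
    """
    out = []
    for a in annots:
        if a.scenario.n_ins != 0 or a.scenario.n_del != 2:
            continue
        dels = sorted(
            (e for e in a.scenario.events if e.kind == "del"), key=lambda e: e.position
        )
        first, second = dels
        out.append(second.position - (first.position + first.length))
    return np.array(out, dtype=int)


def positional_profiles(
    annots: list[AnnotatedRead], min_coverage_frac: float = 0.02
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-position event rates (template-local coordinates) and their correlations.

    The rate at position ``p`` is the number of events at ``p`` divided by
    the number of reads whose template extends past ``p`` (coverage
    normalization); positions covered by fewer than ``min_coverage_frac``
    of the reads are masked.  Deletions and insertions are counted at
    their start position.  Returns the profile table and a table of
    pairwise Pearson correlations between the three profiles.

    An optional IMGT-style position mapping can be applied by the caller
    to the ``position`` column before pooling across templates.
    """
    if not annots:
        raise ValueError("no annotations")
    max_len = max(a.template.L for a in annots)
    coverage = np.zeros(max_len)
    ev = {k: np.zeros(max_len) for k in ("point", "del", "ins")}
    for a in annots:
        coverage[: a.template.L] += 1
        for e in a.scenario.events:
            if e.position < max_len:
                ev[e.kind][e.position] += 1
    masked = coverage < min_coverage_frac * len(annots)
    if masked.all():
        raise ValueError("all positions are masked; profiles are empty")
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = {k: np.where(coverage > 0, v / coverage, np.nan) for k, v in ev.items()}
    df = pd.DataFrame(
        {
            "position": np.arange(max_len),
            "coverage": coverage,
            "point_rate": rates["point"],
            "del_rate": rates["del"],
            "ins_rate": rates["ins"],
            "masked": masked,
        }
    )
    ok = ~masked & (coverage > 0)
    pairs = [("point", "del"), ("point", "ins"), ("del", "ins")]
    rows = []
    for x, y in pairs:
        a, b = rates[x][ok], rates[y][ok]
        if np.std(a) == 0 or np.std(b) == 0:
            r, p = np.nan, np.nan  # a constant profile has no defined correlation
        else:
            r, p = sps.pearsonr(a, b)
        rows.append({"profile_x": x, "profile_y": y, "r": r, "p": p})
    return df, pd.DataFrame(rows)


def _nearest_distances(
    indel_pos: list[np.ndarray], point_pos: list[np.ndarray], perm: np.ndarray
) -> np.ndarray:
    """Distance from each indel to the nearest point mutation of read perm[i]."""
    out = []
    for i, ips in enumerate(indel_pos):
        pts = point_pos[perm[i]]
        if len(ips) == 0 or len(pts) == 0:
            continue
        for p in ips:
            out.append(int(np.min(np.abs(pts - p))))
    return np.array(out, dtype=int)


def colocalization_null(
    annots: list[AnnotatedRead],
    seed: int = 0,
    max_distance: int = 30,
    n_perm: int = 20,
) -> pd.DataFrame:
    """Indel-to-nearest-SHM distance distribution against a reshuffled null.

    The null reassigns each read's point-mutation positions to another
    read aligned to the same template (random permutation within the
    template group), destroying within-read co-localization while
    preserving positional preferences.  The generative model places
    events independently, so on simulated data the ratio is ~1.
    """
    rng = np.random.default_rng(seed)
    groups: dict[str, list[AnnotatedRead]] = {}
    for a in annots:
        groups.setdefault(a.template.id, []).append(a)
    obs_all, null_all = [], []
    for members in groups.values():
        if len(members) < 2:
            continue
        ipos = [
            np.array([e.position for e in a.scenario.events if e.kind != "point"])
            for a in members
        ]
        ppos = [
            np.array([e.position for e in a.scenario.events if e.kind == "point"])
            for a in members
        ]
        identity = np.arange(len(members))
        obs_all.append(_nearest_distances(ipos, ppos, identity))
        for _ in range(n_perm):
            null_all.append(_nearest_distances(ipos, ppos, rng.permutation(len(members))))
    obs = np.concatenate(obs_all) if obs_all else np.array([], dtype=int)
    null = np.concatenate(null_all) if null_all else np.array([], dtype=int)
    bins = np.arange(max_distance + 2)
    h_obs, _ = np.histogram(obs, bins=bins, density=True) if len(obs) else (np.zeros(max_distance + 1), None)
    h_null, _ = np.histogram(null, bins=bins, density=True) if len(null) else (np.zeros(max_distance + 1), None)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(h_null > 0, h_obs / h_null, np.nan)
    return pd.DataFrame(
        {"distance": bins[:-1], "observed": h_obs, "null": h_null, "ratio": ratio}
    )


def quality_filter(
    annots: list[AnnotatedRead], min_coverage: int = 200
) -> tuple[list[AnnotatedRead], int]:
    """Keep reads whose alignment covers at least ``min_coverage`` template bp."""
    kept = [a for a in annots if a.aligned_bp >= min_coverage]
    return kept, len(annots) - len(kept)


def fit_exponential_length_scale(probs: np.ndarray, min_prob: float = 1e-8) -> float:
    """Characteristic length of an exponentially decaying length distribution.

    Weighted least squares of ``log P(ell)`` on ``ell`` (weights ``P``),
    returning ``-1/slope``; for a truncated geometric profile with scale
    ``s`` this recovers ``s`` exactly.
    """
    probs = np.asarray(probs, dtype=float)
    ell = np.arange(1, len(probs) + 1, dtype=float)
    ok = probs > min_prob
    if ok.sum() < 2:
        raise ValueError("not enough support to fit an exponential")
    x, y, w = ell[ok], np.log(probs[ok]), probs[ok]
    xm = np.average(x, weights=w)
    ym = np.average(y, weights=w)
    slope = np.sum(w * (x - xm) * (y - ym)) / np.sum(w * (x - xm) ** 2)
    if slope >= 0:
        raise ValueError("length distribution does not decay")
    return float(-1.0 / slope)
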