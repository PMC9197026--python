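"""Readers and writers: FASTA sequences, JSON model files, TSV event tables."""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    DEFAULT_THETA_MAX,
    IndelModel,
    LengthDistribution,
    ModelValidationError,
    MuPrior,
    MutationEvent,
    MutationScenario,
    NucleotideSequence,
    TemplateSet,
)

logger = logging.getLogger("shmindel")

MODEL_SCHEMA_VERSION = 1


def read_fasta(path: str | Path) -> list[NucleotideSequence]:
    """Read a FASTA file into :class:`NucleotideSequence` records.

    Records containing symbols outside {A, C, G, T} (e.g. ``N``) are
    skipped with a warning; duplicated ids are deduplicated with a
    numeric suffix.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    out: list[NucleotideSequence] = []
    seen: dict[str, int] = {}
    for rec in records:
        seq = str(rec.seq).upper()
        name = rec.id
        if name in seen:
            seen[name] += 1
            new_name = f"{name}_{seen[name]}"
            warnings.warn(f"duplicated FASTA id {name!r} renamed to {new_name!r}")
            name = new_name
        else:
            seen[name] = 0
        try:
            out.append(NucleotideSequence(id=name, seq=seq))
        except ValueError:
            warnings.warn(f"skipping record {rec.id!r}: non-ACGT symbols")
    if not out:
        raise ValueError(f"no usable (pure-ACGT) records in {path}")
    return out


def write_fasta(sequences: list[NucleotideSequence], path: str | Path) -> None:
    records = [SeqRecord(Seq(s.seq), id=s.id, description="") for s in sequences]
    SeqIO.write(records, str(path), "fasta")


def read_templates(path: str | Path) -> TemplateSet:
    return TemplateSet(read_fasta(path))


# ---------------------------------------------------------------------------
# model (de)serialization
# ---------------------------------------------------------------------------

def model_to_dict(model: IndelModel) -> dict:
    return {
        "schema_version": MODEL_SCHEMA_VERSION,
        "naive_fraction": model.prior.f,
        "mu_bin_width": model.prior.bin_width,
        "mu_density": model.prior.density.tolist(),
        "beta_del": model.beta_del,
        "beta_ins": model.beta_ins,
        "p_del": model.len_del.probs.tolist(),
        "p_ins": model.len_ins.probs.tolist(),
        "theta_max": model.theta_max,
    }


def model_from_dict(doc: dict) -> IndelModel:
    for key in ("naive_fraction", "mu_density", "beta_del", "beta_ins", "p_del", "p_ins"):
        if key not in doc:
            raise ModelValidationError(f"model document is missing field {key!r}")
    theta_max = doc.get("theta_max")
    if theta_max is None:
        warnings.warn(f"model document missing theta_max; defaulting to {DEFAULT_THETA_MAX}")
        theta_max = DEFAULT_THETA_MAX
    p_del = np.asarray(doc["p_del"], dtype=float)
    p_ins = np.asarray(doc["p_ins"], dtype=float)
    if len(p_del) != theta_max or len(p_ins) != theta_max:
        raise ModelValidationError("p_del/p_ins length inconsistent with theta_max")
    if doc["beta_del"] < 0 or doc["beta_ins"] < 0:
        raise ModelValidationError("beta_del and beta_ins must be >= 0")
    prior = MuPrior(
        f=float(doc["naive_fraction"]),
        density=np.asarray(doc["mu_density"], dtype=float),
        bin_width=float(doc.get("mu_bin_width", 0.0005)),
    )
    return IndelModel(
        prior=prior,
        beta_del=float(doc["beta_del"]),
        beta_ins=float(doc["beta_ins"]),
        len_del=LengthDistribution(p_del),
        len_ins=LengthDistribution(p_ins),
    )


def save_model(model: IndelModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh)


def load_model(path: str | Path) -> IndelModel:
    with open(path) as fh:
        return model_from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# event tables
# ---------------------------------------------------------------------------

def scenarios_to_table(scenarios: list[tuple[str, MutationScenario]]) -> pd.DataFrame:
    """Flatten (read_id, scenario) pairs into one row per event."""
    rows = []
    for read_id, sc in scenarios:
        for e in sc.events:
            rows.append(
                {
                    "read_id": read_id,
                    "template_id": sc.template_id,
                    "kind": e.kind,
                    "template_position": e.position,
                    "length": e.length,
                    "inserted_seq": e.inserted_seq,
                    "new_base": e.new_base,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "read_id",
            "template_id",
            "kind",
            "template_position",
            "length",
            "inserted_seq",
            "new_base",
        ],
    )


def write_events_tsv(
    scenarios: list[tuple[str, MutationScenario]], path: str | Path, header_comment: str = ""
) -> None:
    df = scenarios_to_table(scenarios)
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def scenarios_to_json(scenarios: list[tuple[str, MutationScenario]], path: str | Path) -> None:
    doc = [
        {
            "read_id": read_id,
            "template_id": sc.template_id,
            "mu": sc.mu,
            "events": [
                {
                    "kind": e.kind,
                    "position": e.position,
                    "length": e.length,
                    "inserted_seq": e.inserted_seq,
                    "new_base": e.new_base,
                }
                for e in sc.events
            ],
        }
        for read_id, sc in scenarios
    ]
    with open(path, "w") as fh:
        json.dump(doc, fh)


def scenarios_from_json(path: str | Path) -> list[tuple[str, MutationScenario]]:
    with open(path) as fh:
        doc = json.load(fh)
    out = []
    for item in doc:
        events = [MutationEvent(**e) for e in item["events"]]
        out.append(
            (item["read_id"], MutationScenario(item["template_id"], item["mu"], events))
        )
    return out
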