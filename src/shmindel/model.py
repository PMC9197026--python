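"""Model / Results surface for repertoire-level SHM-indel inference.

:class:`RepertoireModel` is built from data (reads plus germline
templates); its :meth:`~RepertoireModel.fit` runs the EM + gradient
maximum-likelihood procedure and returns a :class:`RepertoireResults`
carrying the fitted parameters, the deterministic-annotation baseline,
the optimization trajectory and convenience accessors (``summary()``,
``simulate()``, per-read evaluation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotate import DEFAULT_PENALTIES, DeterministicAnnotation, PenaltySet, annotate_repertoire
from .core import DEFAULT_MU_BIN_WIDTH, IndelModel, NucleotideSequence, TemplateSet
from .inference import (
    FitResult,
    OptimizerConfig,
    build_batch,
    fit as _fit,
    initial_model_from_annotations,
    _posteriors_for_iteration,
)
from .likelihood import PruningConfig
from .simulate import SyntheticRepertoire, generate_repertoire


class RepertoireModel:
    """A repertoire of V-segment reads to be explained by the SHM-indel model.

    Parameters
    ----------
    reads
        Observed reads (V segment only, strict ACGT).
    templates
        Germline V templates the reads may derive from.
    theta_max
        Maximum single-event indel length allowed during inference.
    penalties, pruning
        Deterministic-aligner penalties (used for template selection and
        initialization) and pruning configuration.
    """

    def __init__(
        self,
        reads: list[NucleotideSequence],
        templates: TemplateSet,
        theta_max: int = 30,
        penalties: PenaltySet = DEFAULT_PENALTIES,
        pruning: PruningConfig = PruningConfig(),
        mu_bin_width: float = DEFAULT_MU_BIN_WIDTH,
    ) -> None:
        if not reads:
            raise ValueError("no reads supplied")
        self.reads = reads
        self.templates = templates
        self.theta_max = theta_max
        self.penalties = penalties
        self.pruning = pruning
        self.mu_bin_width = mu_bin_width
        self._annotations: list[DeterministicAnnotation] | None = None

    @classmethod
    def from_fasta(
        cls, reads_path, templates_path, **kwargs
    ) -> "RepertoireModel":
        from .io import read_fasta, read_templates

        return cls(read_fasta(reads_path), read_templates(templates_path), **kwargs)

    @property
    def annotations(self) -> list[DeterministicAnnotation]:
        """Deterministic (best-alignment) annotations, computed lazily."""
        if self._annotations is None:
            self._annotations = annotate_repertoire(
                self.reads, self.templates, self.penalties
            )
        return self._annotations

    def deterministic_estimate(self) -> IndelModel:
        """Parameter estimate read directly off the deterministic annotations."""
        return initial_model_from_annotations(
            self.annotations, self.theta_max, self.mu_bin_width
        )

    def fit(
        self,
        init: IndelModel | None = None,
        config: OptimizerConfig | None = None,
        freeze_phi: bool = False,
        verbose: bool = False,
    ) -> "RepertoireResults":
        result = _fit(
            self.reads,
            self.templates,
            init=init,
            config=config,
            penalties=self.penalties,
            pruning=self.pruning,
            theta_max=self.theta_max,
            bin_width=self.mu_bin_width,
            freeze_phi=freeze_phi,
            verbose=verbose,
        )
        return RepertoireResults(self, result)

    def evaluate(self, model: IndelModel, config: OptimizerConfig | None = None) -> pd.DataFrame:
        """Per-read marginal log-likelihoods under a given model (evaluation mode)."""
        config = config or OptimizerConfig()
        workspaces, batch = build_batch(
            self.reads,
            self.templates,
            model,
            annotations=self.annotations,
            penalties=self.penalties,
            pruning=self.pruning,
        )
        for ws in workspaces:
            ws.n_nodes = config.nodes_low if ws.annotation.n_point < 5 else config.nodes_high
        posteriors = _posteriors_for_iteration(workspaces, batch, model, config)
        return pd.DataFrame(
            {
                "read_id": [s.id for s in self.reads],
                "template_id": [ws.template.id for ws in workspaces],
                "loglik": [p.marginal_loglik for p in posteriors],
                "posterior_naive": [p.f_s for p in posteriors],
                "map_mu": [p.map_mu for p in posteriors],
            }
        )


@dataclass
class RepertoireResults:
    """Fitted SHM-indel model with its provenance and diagnostics."""

    model_data: RepertoireModel
    fit_result: FitResult

    @property
    def params(self) -> IndelModel:
        return self.fit_result.model

    @property
    def deterministic_params(self) -> IndelModel:
        return self.fit_result.init_model

    @property
    def naive_fraction(self) -> float:
        return self.params.prior.f

    @property
    def beta_del(self) -> float:
        return self.params.beta_del

    @property
    def beta_ins(self) -> float:
        return self.params.beta_ins

    @property
    def trajectory(self) -> pd.DataFrame:
        return self.fit_result.trajectory

    @property
    def converged(self) -> bool:
        return self.fit_result.converged

    def posterior_naive_weights(self) -> np.ndarray:
        return np.array([p.f_s for p in self.fit_result.posteriors])

    def summary(self) -> str:
        """Plain-text comparison of probabilistic and deterministic estimates."""
        fitted = self.params
        det = self.deterministic_params
        ll = (
            self.trajectory["loglik"].iloc[-1] if len(self.trajectory) else float("nan")
        )
        lines = [
            "SHM-indel repertoire fit",
            "========================",
            f"reads: {len(self.model_data.reads)}   "
            f"templates: {self.model_data.templates.N_t}   "
            f"theta_max: {fitted.theta_max}",
            f"iterations: {self.fit_result.n_iter}   converged: {self.converged}   "
            f"log-likelihood: {ll:.3f}",
            "",
            f"{'parameter':<28}{'probabilistic':>16}{'deterministic':>16}",
            f"{'naive fraction f':<28}{fitted.prior.f:>16.4f}{det.prior.f:>16.4f}",
            f"{'beta_del':<28}{fitted.beta_del:>16.4f}{det.beta_del:>16.4f}",
            f"{'beta_ins':<28}{fitted.beta_ins:>16.4f}{det.beta_ins:>16.4f}",
            f"{'mean mu (experienced)':<28}"
            f"{fitted.prior.mean_experienced():>16.4f}{det.prior.mean_experienced():>16.4f}",
            f"{'mean deletion length':<28}"
            f"{fitted.len_del.mean():>16.2f}{det.len_del.mean():>16.2f}",
            f"{'mean insertion length':<28}"
            f"{fitted.len_ins.mean():>16.2f}{det.len_ins.mean():>16.2f}",
        ]
        return "\n".join(lines)

    def simulate(self, n: int, seed: int = 0) -> SyntheticRepertoire:
        """Generate a synthetic repertoire from the fitted model (generation mode)."""
        return generate_repertoire(self.model_data.templates, self.params, n, seed=seed)
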