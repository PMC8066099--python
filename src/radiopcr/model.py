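"""Model/Results front end for the full prediction workflow.

``PcrRadiomicsModel`` holds a clean case x feature table (built directly,
from a pandas DataFrame, or by extracting the radiomic bank from a cohort of
volumes). ``fit()`` runs the reproduced protocol end to end — stability
feature selection, repeated-CV model selection over the classifier roster,
final refit of the winner, Youden operating point on the training scores —
and returns a ``PcrRadiomicsResults`` carrying every intermediate report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import RunConfig
from .evaluation import OperatingPoint, RocCurve, roc, youden_optimal
from .features import extract_bank
from .modeling import ModelSelectionReport, evaluate_roster, fit_final
from .selection import SelectionReport, select_features
from .table import FeatureTable, prepare_table

__all__ = ["PcrRadiomicsModel", "PcrRadiomicsResults", "NoFeaturesSelectedError"]


class NoFeaturesSelectedError(RuntimeError):
    """The stability-selection stage retained no feature."""


@dataclass
class PcrRadiomicsResults:
    """Fitted-pipeline results: selection, model ranking, operating point."""

    model: "PcrRadiomicsModel"
    selection: SelectionReport
    model_selection: ModelSelectionReport
    final_estimator: object
    scores: np.ndarray
    roc_curve: RocCurve
    operating_point: OperatingPoint
    prepare_info: dict

    @property
    def winner(self) -> str:
        return self.model_selection.winner

    @property
    def mean_auc(self) -> float:
        return self.model_selection.mean_auc[self.winner]

    def ranking(self) -> pd.DataFrame:
        return self.model_selection.ranking()

    def summary(self) -> str:
        op = self.operating_point
        lines = [
            "pCR radiomics prediction — fit summary",
            "=" * 46,
            f"cases: {self.model.table.n_cases}"
            f"  (pCR: {int(self.model.table.labels.sum())})",
            f"features in table: {self.model.table.n_features}",
            f"stable set: {len(self.selection.stable_set)}"
            f"  -> pruned set: {len(self.selection.pruned_set)}",
            "",
            "Model ranking (mean +/- SD of 24 held-out AUCs):",
            self.ranking().to_string(index=False),
            "",
            f"winner: {self.winner}"
            f"  (mean AUC {self.mean_auc:.2f}"
            f" +/- {self.model_selection.sd_auc[self.winner]:.2f})",
            f"training-set ROC AUC of final model: {self.roc_curve.auc:.3f}",
            f"Youden-optimal threshold: {op.threshold:.3f}  (J = {op.youden_j:.3f})",
            f"sensitivity {op.sensitivity:.1%} | specificity {op.specificity:.1%}"
            f" | accuracy {op.accuracy:.1%}",
        ]
        return "\n".join(lines)

    def to_report(self) -> dict:
        """JSON-serialisable run report (embeds the resolved configuration)."""
        return {
            "config": self.model.config.to_dict(),
            "n_cases": self.model.table.n_cases,
            "n_positive": int(self.model.table.labels.sum()),
            "prepare": self.prepare_info,
            "selection": self.selection.to_dict(),
            "model_selection": self.model_selection.to_dict(),
            "winner": self.winner,
            "training_auc": self.roc_curve.auc,
            "operating_point": self.operating_point.to_dict(),
            "scores": [float(s) for s in self.scores],
            "positive_class": "pCR (pR1/pR2 -> negative)",
        }

    def save_report(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_report(), fh, indent=2, sort_keys=True)


class PcrRadiomicsModel:
    """End-to-end pCR prediction pipeline over a radiomic feature table.

    Parameters
    ----------
    table:
        Case x feature table with binary pCR labels. Missing values are
        handled at construction (mostly-missing features dropped, the rest
        median-imputed).
    config:
        Pipeline settings; defaults reproduce the protocol constants.
    """

    def __init__(self, table: FeatureTable, config: RunConfig | None = None):
        self.config = config or RunConfig()
        self.table, self.prepare_info = prepare_table(
            table, max_missing_frac=self.config.max_missing_frac
        )

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, label_col: str = "label", config: RunConfig | None = None
    ) -> "PcrRadiomicsModel":
        return cls(FeatureTable.from_frame(df, label_col=label_col), config=config)

    @classmethod
    def from_cohort(cls, cohort, config: RunConfig | None = None) -> "PcrRadiomicsModel":
        """Extract the radiomic bank from a cohort of volumes, then build."""
        config = config or RunConfig()
        bank = config.bank_config()
        rows = [extract_bank(case, bank) for case in cohort.cases]
        ids = [str(fid) for fid in rows[0]]
        values = np.array([[row[fid] for fid in rows[0]] for row in rows])
        return cls(FeatureTable(values, ids, cohort.labels), config=config)

    def fit(self) -> PcrRadiomicsResults:
        cfg = self.config
        selection = select_features(
            self.table,
            k=cfg.selection_k,
            alpha=cfg.alpha,
            min_votes=cfg.min_votes,
            r_max=cfg.r_max,
            seed=cfg.seed,
        )
        if not selection.pruned_set:
            raise NoFeaturesSelectedError(
                "no feature survived stability selection; nothing to model"
            )
        selected = self.table.subset(selection.pruned_set)
        model_selection = evaluate_roster(
            selected,
            roster=cfg.roster,
            k=cfg.cv_k,
            repeats=cfg.cv_repeats,
            seed=cfg.seed,
        )
        estimator, scores = fit_final(selected, model_selection.winner, seed=cfg.seed)
        curve = roc(scores, selected.labels)
        return PcrRadiomicsResults(
            model=self,
            selection=selection,
            model_selection=model_selection,
            final_estimator=estimator,
            scores=scores,
            roc_curve=curve,
            operating_point=youden_optimal(curve),
            prepare_info=self.prepare_info,
        )
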