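"""High-level drivers chaining the screening and scoring stages."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import clustering, correlation, descriptives, factors, selection, standardization, scoring

__all__ = ["ScreenResult", "screen_table", "evaluate_table"]


@dataclass(frozen=True)
class ScreenResult:
    summary: pd.DataFrame
    cm: correlation.CorrelationMatrix
    flags: correlation.FlagMatrix
    flag_counts: tuple[int, int, int]
    factor_model: factors.FactorModel
    factor_assign: dict
    cluster_assign: dict
    consensus: selection.ConsensusClasses
    representatives: selection.RepresentativeSet

    def report(self) -> dict:
        """JSON-ready selection report."""
        n_pairs, n_p05, n_p01 = self.flag_counts
        return {
            "n_samples": self.cm.n,
            "n_indexes": len(self.cm.names),
            "flag_counts": {"pairs": n_pairs, "p05_only": n_p05, "p01": n_p01},
            "retained_factors": self.factor_model.retained_k,
            "cumulative_contribution_pct": float(self.factor_model.cumulative[-1]),
            "classes": [list(c) for c in self.consensus.classes],
            "provenance": dict(self.consensus.provenance),
            "representatives": list(self.representatives.representatives),
            "rationale": list(self.representatives.rationale),
        }


def screen_table(
    table: pd.DataFrame,
    *,
    n_classes: int = 5,
    cv_summary: pd.DataFrame | None = None,
) -> ScreenResult:
    """Run the full index screen on a variety x index table.

    Stages: descriptives -> correlation + flags -> principal-component
    factoring (Kaiser retention, varimax) -> Ward variable clustering cut
    at *n_classes* -> consensus classes -> max-|CV| representatives.

    ``cv_summary`` optionally substitutes an external descriptive summary
    (e.g. the published panel statistics) for the CV-driven selection
    step, which matters when *table* is a small resample whose CVs are
    noisy.
    """
    summary = descriptives.summarize(table)
    cm = correlation.correlation_matrix(table)
    flags = correlation.flag_significance(cm)
    model = factors.rotate_varimax(factors.extract_factors(cm))
    f_assign = factors.assign_to_factors(model)
    tree = clustering.ward_cluster(table)
    c_assign = clustering.cut_tree(tree, n_classes)
    consensus = selection.consensus_classes(f_assign, c_assign, flags, cm,
                                            n_classes=n_classes)
    reps = selection.select_representatives(
        consensus, cv_summary if cv_summary is not None else summary)
    return ScreenResult(
        summary=summary,
        cm=cm,
        flags=flags,
        flag_counts=correlation.count_flags(flags),
        factor_model=model,
        factor_assign=f_assign,
        cluster_assign=c_assign,
        consensus=consensus,
        representatives=reps,
    )


def evaluate_table(
    table: pd.DataFrame,
    *,
    weights: dict[str, float] | None = None,
    spec: standardization.IdealSpec | None = None,
    renormalize: bool = False,
) -> pd.DataFrame:
    """Standardize and score a table of representative-index measurements.

    Returns a frame with the standardized ``X_<index>`` columns, the
    composite ``Y`` and the competition rank, sorted best first.
    """
    X = standardization.standardize_table(table, spec)
    scores = scoring.comprehensive_score(X, weights, renormalize=renormalize)
    ranked = scoring.rank_samples(scores)
    out = X.add_prefix("X_").join(ranked)
    return out.sort_values(["rank", "Y"], ascending=[True, False])
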