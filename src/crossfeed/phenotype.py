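"""Phenotype-array emulation: sole-carbon-source growth calls vs observation.

Mirrors how genome-scale models are validated against phenotype
microarrays (e.g. Biolog PM1): for each candidate carbon source, open
only that source's exchange on top of a carbon-free base medium, solve
FBA, and call growth when the optimum clears a threshold.  Predictions
are then scored against an observed truth table as a confusion matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .community import apply_medium_to_model
from .core import StoichiometricModel
from .solver import SolverConfig, fba

__all__ = [
    "PhenotypeComparison",
    "ConfigurationError",
    "simulate_carbon_sources",
    "score_phenotypes",
    "comparison_report",
]

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    """The validation setup is self-defeating (e.g. base medium already grows)."""


@dataclass
class PhenotypeComparison:
    """Predicted vs observed growth calls with confusion-matrix tallies."""

    per_source: Dict[str, Tuple[bool, bool]] = field(default_factory=dict)
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n if self.n else float("nan")


def simulate_carbon_sources(
    model: StoichiometricModel,
    sources: Sequence[str],
    base_medium: Mapping[str, float],
    uptake_bound: float = 10.0,
    growth_threshold: float = 1e-6,
    config: Optional[SolverConfig] = None,
) -> Dict[str, bool]:
    """Predict growth (True/False) per sole carbon source.

    ``base_medium`` must be carbon-free: if the model already grows on it,
    every call would come back positive, so that is rejected as a
    configuration error.  Sources with no matching exchange reaction in
    the model are excluded from the result and logged.
    """
    config = config or SolverConfig()
    base = apply_medium_to_model(model, base_medium)
    baseline = fba(base, config)
    if baseline.optimal and baseline.objective_value > growth_threshold:
        raise ConfigurationError(
            f"base medium already supports growth (objective "
            f"{baseline.objective_value:.3g} > threshold {growth_threshold:g}); "
            "it must be carbon-free"
        )

    by_base_id: Dict[str, str] = {}
    for r in base.reactions:
        if r.is_exchange:
            (met_id,) = r.stoichiometry
            by_base_id[base.metabolite(met_id).base_id] = r.id

    predictions: Dict[str, bool] = {}
    unmappable: List[str] = []
    for source in sources:
        rid = by_base_id.get(source)
        if rid is None:
            unmappable.append(source)
            continue
        probe = base.copy()
        probe.reaction(rid).lower_bound = -float(uptake_bound)
        sol = fba(probe, config)
        predictions[source] = bool(
            sol.optimal and sol.objective_value > growth_threshold
        )
    if unmappable:
        logger.warning("sources with no exchange in model %s (excluded): %s",
                       model.id, unmappable)
    return predictions


def score_phenotypes(
    predicted: Mapping[str, bool], observed: Mapping[str, bool]
) -> PhenotypeComparison:
    """Confusion-matrix comparison over the shared carbon sources.

    Scoring is restricted to the key intersection; sources present on one
    side only are logged and excluded.
    """
    shared = sorted(set(predicted) & set(observed))
    if not shared:
        raise ValueError("predicted and observed share no carbon sources")
    dropped = sorted(set(predicted).symmetric_difference(observed))
    if dropped:
        logger.warning("sources excluded from scoring (present on one side only): %s",
                       dropped)
    cmp = PhenotypeComparison()
    for source in shared:
        p, o = bool(predicted[source]), bool(observed[source])
        cmp.per_source[source] = (p, o)
        if p and o:
            cmp.tp += 1
        elif p and not o:
            cmp.fp += 1
        elif not p and not o:
            cmp.tn += 1
        else:
            cmp.fn += 1
    return cmp


def comparison_report(
    cmp: PhenotypeComparison,
    uptake_bound: float = 10.0,
    growth_threshold: float = 1e-6,
) -> str:
    """Per-source TSV plus a summary line, with the knobs in the header."""
    lines = [
        f"# uptake_bound={uptake_bound:g} growth_threshold={growth_threshold:g}",
        "source_id\tpredicted\tobserved",
    ]
    for source, (p, o) in sorted(cmp.per_source.items()):
        lines.append(f"{source}\t{int(p)}\t{int(o)}")
    lines.append(
        f"# summary\ttp={cmp.tp}\tfp={cmp.fp}\ttn={cmp.tn}\tfn={cmp.fn}\t"
        f"accuracy={cmp.accuracy:.4f}"
    )
    return "\n".join(lines) + "\n"
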