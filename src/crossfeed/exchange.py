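"""Interspecies exchange calls from a community flux solution.

A metabolite is *exchanged* when one species' transfer reaction moves it
into the shared compartment while the other species' transfer moves it
out, in the same solution.  The transferred amount is
``min(secretion, uptake)``: the shared-compartment mass balance makes the
two agree up to the community-exchange term, and the minimum is what
actually passed between the species rather than leaking to the
environment.

Because pFBA returns one of possibly many optima, each record carries a
``robust`` qualifier from FVA: robust means the optimal face admits no
solution in which either transfer flux drops to zero or changes sign.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .community import SHARED_COMPARTMENT, CommunityModel
from .core import base_id
from .solver import FluxSolution, SolverConfig, fva

__all__ = [
    "ExchangeRecord",
    "interspecies_exchanges",
    "classify_exchanges",
    "exchange_report",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExchangeRecord:
    """One metabolite crossing the shared space from donor to receiver."""

    metabolite_base_id: str
    metabolite_name: str
    donor: str
    receiver: str
    flux: float  # mmol gDW^-1 h^-1, amount transferred between species
    category: str = "other"
    robust: bool = False

    def __post_init__(self) -> None:
        if self.donor == self.receiver:
            raise ValueError("donor and receiver must differ")
        if self.flux <= 0:
            raise ValueError("exchange flux must be positive")


def interspecies_exchanges(
    community: CommunityModel,
    solution: FluxSolution,
    config: Optional[SolverConfig] = None,
    compute_robust: bool = True,
) -> List[ExchangeRecord]:
    """Extract donor->receiver exchange records from an optimal solution.

    For each shared metabolite: donor = species whose transfer flux into
    ``e`` exceeds ``zero_cut``, receiver = species whose transfer flux out
    of ``e`` exceeds ``zero_cut``.  Records are sorted by descending flux
    (ties by metabolite id); at most one record per metabolite per
    direction.
    """
    config = config or SolverConfig()
    if not solution.optimal:
        raise ValueError(f"solution status is {solution.status!r}, need optimal")
    model_ids = set(community.base.reaction_ids)
    if set(solution.fluxes) != model_ids:
        raise ValueError(
            "solution is keyed to a different model: "
            f"{sorted(model_ids.symmetric_difference(solution.fluxes))[:5]} ..."
        )

    candidates: List[Tuple[str, str, str, float, str, str]] = []
    for e_id, per_species in community.transfer_map.items():
        flows = {tag: solution.fluxes[rid] for tag, rid in per_species.items()}
        donors = {t: v for t, v in flows.items() if v > config.zero_cut}
        receivers = {t: -v for t, v in flows.items() if v < -config.zero_cut}
        if not donors or not receivers:
            continue
        met = community.base.metabolite(e_id)
        for d_tag, sec in donors.items():
            for r_tag, upt in receivers.items():
                candidates.append(
                    (e_id, d_tag, r_tag, min(sec, upt), met.name, met.category or "other")
                )

    fva_ranges: Dict[str, Tuple[float, float]] = {}
    if compute_robust and candidates:
        rxn_ids = sorted(
            {
                community.transfer_map[e_id][tag]
                for e_id, d, r, _, _, _ in candidates
                for tag in (d, r)
            }
        )
        fva_ranges = fva(community.base, rxn_ids, config)

    records: List[ExchangeRecord] = []
    for e_id, d_tag, r_tag, flux, name, category in candidates:
        robust = False
        if fva_ranges:
            d_lo, d_hi = fva_ranges[community.transfer_map[e_id][d_tag]]
            r_lo, r_hi = fva_ranges[community.transfer_map[e_id][r_tag]]
            robust = d_lo > config.zero_cut and r_hi < -config.zero_cut
        records.append(
            ExchangeRecord(
                metabolite_base_id=base_id(e_id, SHARED_COMPARTMENT),
                metabolite_name=name,
                donor=d_tag,
                receiver=r_tag,
                flux=flux,
                category=category,
                robust=robust,
            )
        )
    records.sort(key=lambda rec: (-rec.flux, rec.metabolite_base_id, rec.donor))
    return records


def classify_exchanges(
    records: Sequence[ExchangeRecord],
    annotation: Optional[Mapping[str, str]] = None,
) -> Dict[str, int]:
    """Tally exchange records by metabolite category.

    ``annotation`` (base id -> category) overrides the categories already
    stamped on the records; uncovered metabolites fall into ``other`` and
    are logged.  The counts always partition the records.
    """
    counts: Dict[str, int] = {}
    uncovered = []
    for rec in records:
        if annotation is not None:
            cat = annotation.get(rec.metabolite_base_id)
            if cat is None:
                uncovered.append(rec.metabolite_base_id)
                cat = "other"
        else:
            cat = rec.category or "other"
        counts[cat] = counts.get(cat, 0) + 1
    if uncovered:
        logger.warning("metabolites without category annotation -> 'other': %s",
                       sorted(set(uncovered)))
    return counts


def exchange_report(
    records: Sequence[ExchangeRecord],
    fva_ranges: Optional[Mapping[str, Tuple[float, float]]] = None,
    config: Optional[SolverConfig] = None,
) -> str:
    """Render records as a TSV with the solver config in the header.

    ``fva_ranges`` is keyed by metabolite base id (transfer-flux range of
    the donor side); absent ranges render as empty fields.
    """
    config = config or SolverConfig()
    lines = [
        f"# solver: feas_tol={config.feas_tol:g} "
        f"opt_fraction={config.opt_fraction:g} zero_cut={config.zero_cut:g}",
        "\t".join(
            [
                "metabolite_base_id", "name", "donor", "receiver",
                "flux", "category", "robust", "fva_min", "fva_max",
            ]
        ),
    ]
    for rec in records:
        lo, hi = ("", "")
        if fva_ranges and rec.metabolite_base_id in fva_ranges:
            lo_f, hi_f = fva_ranges[rec.metabolite_base_id]
            lo, hi = f"{lo_f:.6g}", f"{hi_f:.6g}"
        flux = 0.0 if abs(rec.flux) < config.zero_cut else rec.flux
        lines.append(
            "\t".join(
                [
                    rec.metabolite_base_id,
                    rec.metabolite_name,
                    rec.donor,
                    rec.receiver,
                    f"{flux:.6g}",
                    rec.category,
                    str(rec.robust).lower(),
                    lo,
                    hi,
                ]
            )
        )
    return "\n".join(lines) + "\n"
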