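"""Intersection of two engines' accepted PSMs.

Most wrong matches are engine-specific: two search engines rarely agree on
the same wrong peptide for the same spectrum.  Keeping only PSMs where both
engines report the identical match (same spectrum, same modified peptide,
same charge) therefore removes a large share of the residual error at a
small cost in sensitivity.  I and L are treated as distinct here — both
engines searched the same database, so truly identical matches agree on
the reported residue; I/L equivalence applies only to proteome
classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from newance.io_formats import Group, PsmRecord, normalize_modified_peptide

__all__ = ["CombinedPsm", "IntersectionReport", "intersect_psms", "psms_to_peptides"]


@dataclass(slots=True)
class CombinedPsm:
    spectrum_key: str
    peptide: str
    charge: int
    group: Group
    lfdr_engineA: float
    engineB_score: float
    protein_ids: tuple[str, ...]


@dataclass(slots=True)
class IntersectionReport:
    n_engineA: int = 0
    n_engineB: int = 0
    n_intersection: int = 0
    dropped_engineA_only: int = 0
    dropped_engineB_only: int = 0
    per_group: dict = field(default_factory=dict)


def _key(r: PsmRecord) -> tuple[str, str, int]:
    return (r.spectrum_key, normalize_modified_peptide(r.peptide), r.charge)


def intersect_psms(
    acceptedA: list[PsmRecord],
    acceptedB: list[PsmRecord],
    lfdrA: dict | None = None,
) -> tuple[list[CombinedPsm], IntersectionReport]:
    """Retain PSMs with identical matches in both engines.

    Join key: (spectrum_key, normalised modified peptide, charge).  Both
    inputs must be decoy-free (post-threshold).  The group label is taken
    from engine A and checked for consistency against engine B.  PSMs seen
    by only one engine are dropped and counted in the report.

    ``lfdrA`` optionally maps the engine-A join key to its lFDR value.
    """
    for name, lst in (("engineA", acceptedA), ("engineB", acceptedB)):
        if any(r.is_decoy for r in lst):
            raise ValueError(f"{name} accepted list contains decoy PSMs")
    mapB = {_key(r): r for r in acceptedB}
    lfdrA = lfdrA or {}
    combined: list[CombinedPsm] = []
    seen = set()
    for ra in acceptedA:
        key = _key(ra)
        rb = mapB.get(key)
        if rb is None:
            continue
        if (
            rb.group != Group.unassigned
            and ra.group != Group.unassigned
            and rb.group != ra.group
        ):
            raise ValueError(f"conflicting group labels for PSM {key}")
        seen.add(key)
        combined.append(
            CombinedPsm(
                spectrum_key=ra.spectrum_key,
                peptide=normalize_modified_peptide(ra.peptide),
                charge=ra.charge,
                group=ra.group,
                lfdr_engineA=float(lfdrA.get(key, float("nan"))),
                engineB_score=rb.engine_score,
                protein_ids=tuple(dict.fromkeys((*ra.protein_ids, *rb.protein_ids))),
            )
        )
    report = IntersectionReport(
        n_engineA=len(acceptedA),
        n_engineB=len(acceptedB),
        n_intersection=len(combined),
        dropped_engineA_only=len(acceptedA) - len(combined),
        dropped_engineB_only=len(acceptedB) - len(seen),
        per_group={
            g.value: sum(c.group == g for c in combined)
            for g in (Group.proteome, Group.noncanonical, Group.unassigned)
        },
    )
    return combined, report


def psms_to_peptides(
    combined: list[CombinedPsm],
) -> list[tuple[str, Group, int, float]]:
    """Collapse PSMs to unique peptides with PSM counts and best (min) lFDR.

    Output is ordered by (group, peptide) for determinism.
    """
    agg: dict[tuple[str, Group], tuple[int, float]] = {}
    for c in combined:
        key = (c.peptide, c.group)
        n, best = agg.get(key, (0, float("inf")))
        v = c.lfdr_engineA
        if v == v:  # ignore NaN lFDRs in the minimum
            best = min(best, v)
        agg[key] = (n + 1, best)
    out = [
        (peptide, group, n, best if best != float("inf") else float("nan"))
        for (peptide, group), (n, best) in agg.items()
    ]
    out.sort(key=lambda t: (t[1].value, t[0]))
    return out
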