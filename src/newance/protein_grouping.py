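"""Parsimony protein grouping and HLA-sampling statistics.

Final peptides are assigned to protein groups by greedy set cover over the
peptide-protein bipartite graph: the protein explaining the most still
unexplained peptides is selected as a group lead (ties broken by
lexicographically smallest accession), and every protein sharing a peptide
with a lead joins that lead's group.  Within a group, members are sorted by
decreasing peptide count and each member's *adjusted* count is the number
of its peptides not already credited to a member higher up the list, so
the adjusted counts of a group sum to its distinct peptides.  HLA sampling
is the adjusted count divided by protein length — a per-protein
presentation-efficiency proxy comparable across proteins of different
size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "ProteinGroup",
    "GroupMember",
    "group_proteins",
    "adjusted_counts",
    "hla_sampling",
    "expression_sampling_correlation",
]


@dataclass(slots=True)
class GroupMember:
    accession: str
    protein_length: int = 0
    total_peptides: int = 0
    unique_peptides: int = 0
    adjusted_peptides: int = 0
    peptides: frozenset[str] = frozenset()


@dataclass(slots=True)
class ProteinGroup:
    group_id: str  # lead accession
    members: list[GroupMember] = field(default_factory=list)

    @property
    def distinct_peptides(self) -> frozenset[str]:
        out: set[str] = set()
        for m in self.members:
            out |= m.peptides
        return frozenset(out)


def group_proteins(
    peptide_to_proteins: dict[str, set[str]],
    protein_lengths: dict[str, int] | None = None,
) -> list[ProteinGroup]:
    """Greedy parsimony grouping of proteins by shared peptide evidence.

    Repeatedly selects the protein explaining the most not-yet-explained
    peptides (ties: lexicographically smallest accession) as a group lead;
    proteins sharing any peptide with a lead join its group (first lead by
    selection order wins when several would claim the same protein).
    Proteins without peptides never appear.  Members arrive sorted by
    decreasing total peptide count (ties by accession) with total, unique
    and adjusted counts filled in.

    For accounting purposes each peptide belongs to exactly one group —
    the first selected group containing it — so adjusted counts sum to
    the number of distinct peptides over all groups.
    """
    protein_lengths = protein_lengths or {}
    protein_to_peptides: dict[str, set[str]] = {}
    for peptide, accs in peptide_to_proteins.items():
        if not accs:
            raise ValueError(f"peptide {peptide!r} maps to no protein")
        for acc in accs:
            protein_to_peptides.setdefault(acc, set()).add(peptide)

    unexplained = set(peptide_to_proteins)
    leads: list[str] = []
    while unexplained:
        lead = min(
            protein_to_peptides,
            key=lambda acc: (-len(protein_to_peptides[acc] & unexplained), acc),
        )
        gain = protein_to_peptides[lead] & unexplained
        if not gain:  # cannot happen while peptides remain, guards malformed input
            break
        leads.append(lead)
        unexplained -= gain

    # attach member proteins to the first lead they share a peptide with; a
    # selected protein already absorbed into an earlier group heads no group
    # of its own (its remaining peptides stay with that group)
    assigned: dict[str, str] = {}
    group_leads: list[str] = []
    for lead in leads:
        if lead not in assigned:
            group_leads.append(lead)
            assigned[lead] = lead
        home = assigned[lead]
        for peptide in protein_to_peptides[lead]:
            for acc in peptide_to_proteins[peptide]:
                assigned.setdefault(acc, home)

    # each peptide is credited to the first group (by lead order) containing it
    peptide_home: dict[str, str] = {}
    for lead in group_leads:
        group_accs = [a for a, l in assigned.items() if l == lead]
        for acc in group_accs:
            for peptide in protein_to_peptides[acc]:
                peptide_home.setdefault(peptide, lead)

    groups: list[ProteinGroup] = []
    for lead in group_leads:
        group_accs = sorted(a for a, l in assigned.items() if l == lead)
        members = []
        for acc in group_accs:
            peps = frozenset(
                p for p in protein_to_peptides[acc] if peptide_home[p] == lead
            )
            unique = sum(1 for p in peps if len(peptide_to_proteins[p]) == 1)
            members.append(
                GroupMember(
                    accession=acc,
                    protein_length=protein_lengths.get(acc, 0),
                    total_peptides=len(protein_to_peptides[acc]),
                    unique_peptides=unique,
                    peptides=peps,
                )
            )
        group = ProteinGroup(group_id=lead, members=members)
        adjusted_counts(group)
        groups.append(group)
    return groups


def adjusted_counts(group: ProteinGroup) -> ProteinGroup:
    """Fill in adjusted peptide counts for a group's members, in place.

    Members are sorted by decreasing peptide count (ties by accession);
    member k is credited only with peptides not already claimed by members
    1..k-1, so the first member's adjusted count equals its distinct
    peptides and the adjusted counts sum to the group's distinct peptides.
    """
    for m in group.members:
        if m.total_peptides == 0:
            m.total_peptides = len(m.peptides)
    group.members.sort(key=lambda m: (-m.total_peptides, m.accession))
    claimed: set[str] = set()
    for m in group.members:
        fresh = set(m.peptides) - claimed
        m.adjusted_peptides = len(fresh)
        claimed |= fresh
    return group


def hla_sampling(group: ProteinGroup) -> dict[str, float]:
    """Length-normalised HLA sampling per member: adjusted peptides / length."""
    out: dict[str, float] = {}
    for m in group.members:
        if m.protein_length <= 0:
            raise ValueError(f"protein {m.accession!r} has non-positive length")
        out[m.accession] = m.adjusted_peptides / m.protein_length
    return out


def expression_sampling_correlation(
    sampling: dict[str, float],
    expression: dict[str, float],
    log_transform: bool = True,
) -> tuple[np.ndarray, float]:
    """Cubic fit of HLA sampling on (log) expression, with Pearson r.

    A degree-3 polynomial is least-squares fitted to sampling as a
    function of log10(expression + 1) over the genes shared by both maps;
    the returned Pearson correlation is between the fitted curve and the
    observed sampling values.  Needs at least 5 shared genes; a constant
    sampling vector has no defined correlation and yields NaN with a
    warning.
    """
    shared = sorted(set(sampling) & set(expression))
    if len(shared) < 5:
        raise ValueError(f"need >= 5 shared genes, got {len(shared)}")
    y = np.array([sampling[g] for g in shared], dtype=float)
    x = np.array([expression[g] for g in shared], dtype=float)
    if log_transform:
        if np.any(x < 0):
            raise ValueError("expression values must be >= 0")
        x = np.log10(x + 1.0)
    coeffs = np.polyfit(x, y, deg=3)
    fitted = np.polyval(coeffs, x)
    if np.ptp(y) == 0 or np.ptp(fitted) == 0:
        warnings.warn("constant values: Pearson correlation undefined", UserWarning)
        return coeffs, float("nan")
    r, _ = stats.pearsonr(fitted, y)
    return coeffs, float(r)
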