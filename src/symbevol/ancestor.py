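"""Ancestral gene-content reconstruction and lineage event assignment.

A family is called ancestral to the ingroup genus under either of two
conditions: (C1) it is present in every ingroup lineage and intact in at
least one ingroup genome, or (C2) it is intact in at least one ingroup
lineage and present in at least one outgroup genome. A family present in
every ingroup genome but intact in none is flagged ancestrally inactivated
(pseudogenized before the ingroup radiation) and reported separately, not
counted in the ancestral set. Families consisting entirely of mobile
elements (phage, plasmid island, transposase, toxin/antitoxin) are removed
from the reconstruction because horizontal transfer between an outgroup and
an ingroup genome would otherwise masquerade as ancestral presence; the
protective APSE phage and the non-integrated plasmid are exempt from this
exclusion.

Each ancestral family is then classified per ingroup lineage as retained
(intact somewhere in the lineage), inactivated (present but pseudogene-only)
or lost (absent from every genome of the lineage), and lineage loss counts
are compared with a Pearson chi-square test on the 2x2 lost/not-lost table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Optional

from scipy import stats

from .families import FamilyPartition, StateMatrix
from .records import EXCLUDED_MOBILE, GenomeSet

CONDITIONS = ("C1", "C2", "both", "none")


@dataclass
class AncestralCall:
    family_id: str
    ancestral: bool
    condition: str
    ancestrally_inactivated: bool = False
    excluded_mobile: bool = False

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"bad condition {self.condition!r}")
        if self.ancestral and self.condition == "none":
            raise ValueError(f"{self.family_id}: ancestral without a condition")
        if self.excluded_mobile and (self.ancestral or self.condition != "none"):
            raise ValueError(f"{self.family_id}: excluded family cannot be ancestral")


def mobile_excluded_families(
    partition: FamilyPartition, genomeset: GenomeSet
) -> set[str]:
    """Families whose every member is a mobile element, unless any member is
    APSE or the non-integrated plasmid (exempt). Mixed families are treated
    as non-mobile."""
    idx = genomeset.gene_index()
    excluded: set[str] = set()
    for fid in partition.family_ids:
        cats = {idx[g].mobile_category for g in partition.members(fid)}
        if "none" in cats:
            continue
        if cats & {"APSE", "pHD5AT"}:
            continue
        if cats <= EXCLUDED_MOBILE:
            excluded.add(fid)
    return excluded


def _lineage_present(
    sm: StateMatrix, fid: str, genomes: set[str], mode: str
) -> bool:
    hits = [sm.present(fid, g) for g in genomes]
    return all(hits) if mode == "all" else any(hits)


def _lineage_intact(
    sm: StateMatrix, fid: str, genomes: set[str], mode: str
) -> bool:
    hits = [sm.state(fid, g) == "intact" for g in genomes]
    return all(hits) if mode == "all" else any(hits)


def call_ancestral(
    state_matrix: StateMatrix,
    lineages: dict[str, set[str]],
    outgroup_ids: Iterable[str],
    excluded: Optional[set[str]] = None,
    clade_presence: str = "any",
) -> list[AncestralCall]:
    """Apply the two presence conditions family by family.

    ``lineages`` maps lineage name -> set of ingroup genome ids (a named
    clade or a singleton); at least two lineages are required.
    ``clade_presence`` controls whether presence/intactness "in a lineage"
    means any member genome (default) or all of them.
    """
    if clade_presence not in ("any", "all"):
        raise ValueError("clade_presence must be 'any' or 'all'")
    if len(lineages) < 2:
        raise ValueError("at least two ingroup lineages are required")
    outgroups = sorted(outgroup_ids)
    ingroup_genomes = sorted(set().union(*lineages.values()))
    excluded = excluded or set()

    calls: list[AncestralCall] = []
    for fid in state_matrix.family_ids:
        if fid in excluded:
            calls.append(AncestralCall(fid, False, "none", excluded_mobile=True))
            continue
        present_all_lineages = all(
            _lineage_present(state_matrix, fid, g, clade_presence)
            for g in lineages.values()
        )
        intact_any_ingroup = any(
            state_matrix.state(fid, g) == "intact" for g in ingroup_genomes
        )
        intact_any_lineage = any(
            _lineage_intact(state_matrix, fid, g, clade_presence)
            for g in lineages.values()
        )
        present_any_outgroup = any(state_matrix.present(fid, g) for g in outgroups)

        c1 = present_all_lineages and intact_any_ingroup
        c2 = intact_any_lineage and present_any_outgroup
        inactivated = (
            all(state_matrix.present(fid, g) for g in ingroup_genomes)
            and not intact_any_ingroup
        )
        condition = "both" if (c1 and c2) else "C1" if c1 else "C2" if c2 else "none"
        calls.append(
            AncestralCall(
                fid,
                ancestral=c1 or c2,
                condition=condition,
                ancestrally_inactivated=inactivated,
            )
        )
    return calls


@dataclass
class LineageEventTable:
    """Per-lineage partition of the ancestral families plus acquisitions."""

    lineages: dict[str, set[str]]
    losses: dict[str, list[str]] = field(default_factory=dict)
    inactivations: dict[str, list[str]] = field(default_factory=dict)
    retained: dict[str, list[str]] = field(default_factory=dict)
    acquisitions: dict[str, list[str]] = field(default_factory=dict)
    n_ancestral: int = 0

    def counts(self, lineage: str) -> dict[str, int]:
        return {
            "losses": len(self.losses[lineage]),
            "inactivations": len(self.inactivations[lineage]),
            "retained": len(self.retained[lineage]),
            "acquisitions": len(self.acquisitions[lineage]),
        }

    def write_tsv(self, path) -> None:
        with open(path, "w", newline="\n") as fh:
            fh.write("lineage\tevent\tfamily_id\n")
            for lineage in sorted(self.lineages):
                for name, table in (
                    ("loss", self.losses),
                    ("inactivation", self.inactivations),
                    ("retained", self.retained),
                    ("acquisition", self.acquisitions),
                ):
                    for fid in table[lineage]:
                        fh.write(f"{lineage}\t{name}\t{fid}\n")


def assign_lineage_events(
    calls: list[AncestralCall],
    state_matrix: StateMatrix,
    lineages: dict[str, set[str]],
    outgroup_ids: Iterable[str],
) -> LineageEventTable:
    """Classify each ancestral family per lineage as lost, inactivated or
    retained (presence in any genome of a lineage overrides absence; intact
    overrides pseudogene), and list lineage-specific acquisitions."""
    outgroups = sorted(outgroup_ids)
    table = LineageEventTable(lineages=dict(lineages))
    ancestral = [c.family_id for c in calls if c.ancestral]
    non_ancestral = [
        c.family_id for c in calls if not c.ancestral and not c.excluded_mobile
    ]
    table.n_ancestral = len(ancestral)
    for lineage, genomes in lineages.items():
        lost, inact, kept, acq = [], [], [], []
        for fid in ancestral:
            states = [state_matrix.state(fid, g) for g in genomes]
            if "intact" in states:
                kept.append(fid)
            elif "pseudogene" in states:
                inact.append(fid)
            else:
                lost.append(fid)
        other_ingroup = set().union(
            *(g for name, g in lineages.items() if name != lineage)
        )
        for fid in non_ancestral:
            here = any(state_matrix.present(fid, g) for g in genomes)
            elsewhere = any(
                state_matrix.present(fid, g) for g in (*other_ingroup, *outgroups)
            )
            if here and not elsewhere:
                acq.append(fid)
        table.losses[lineage] = lost
        table.inactivations[lineage] = inact
        table.retained[lineage] = kept
        table.acquisitions[lineage] = acq
    return table


@dataclass
class LossComparison:
    """Pearson chi-square comparison of loss counts between two lineages."""

    lineage_a: str
    lineage_b: str
    table: list[list[int]]  # [[lost_a, not_lost_a], [lost_b, not_lost_b]]
    chi2: Optional[float]
    df: int
    p_value: Optional[float]
    valid: bool
    reason: str = ""

    def to_json(self) -> str:
        return json.dumps(
            {
                "lineage_a": self.lineage_a,
                "lineage_b": self.lineage_b,
                "table": self.table,
                "chi2": self.chi2,
                "df": self.df,
                "p_value": self.p_value,
                "valid": self.valid,
                "reason": self.reason,
            },
            indent=2,
        )


def pearson_chi2_2x2(table: list[list[int]]) -> tuple[float, float]:
    """Pearson chi-square without continuity correction, df = 1."""
    (a, b), (c, d) = table
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        raise ZeroDivisionError("zero margin")
    chi2 = n * (a * d - b * c) ** 2 / denom
    return chi2, float(stats.chi2.sf(chi2, df=1))


def compare_loss_counts(
    events: LineageEventTable,
    lineage_a: str,
    lineage_b: str,
    method: str = "2x2",
) -> LossComparison:
    """Compare lineage loss counts over the shared ancestral universe.

    ``method="2x2"`` (default) tests lost vs not-lost between the lineages;
    ``method="gof"`` is a goodness-of-fit chi-square on the two raw loss
    counts against an equal split.
    """
    la, lb = len(events.losses[lineage_a]), len(events.losses[lineage_b])
    n = events.n_ancestral
    table = [[la, n - la], [lb, n - lb]]
    if method == "gof":
        total = la + lb
        if total == 0:
            return LossComparison(
                lineage_a, lineage_b, table, None, 1, None, False, "no losses"
            )
        exp = total / 2.0
        chi2 = (la - exp) ** 2 / exp + (lb - exp) ** 2 / exp
        return LossComparison(
            lineage_a, lineage_b, table, chi2, 1, float(stats.chi2.sf(chi2, 1)), True
        )
    if method != "2x2":
        raise ValueError("method must be '2x2' or 'gof'")
    try:
        chi2, p = pearson_chi2_2x2(table)
    except ZeroDivisionError:
        return LossComparison(
            lineage_a, lineage_b, table, None, 1, None, False, "zero margin"
        )
    return LossComparison(lineage_a, lineage_b, table, chi2, 1, p, True)


@dataclass
class AncestralReconstruction:
    """Bundle of the reconstruction outputs with a printable summary."""

    calls: list[AncestralCall]
    events: LineageEventTable
    comparison: Optional[LossComparison] = None

    @property
    def ancestral_families(self) -> list[str]:
        return sorted(c.family_id for c in self.calls if c.ancestral)

    @property
    def ancestrally_inactivated(self) -> list[str]:
        return sorted(
            c.family_id for c in self.calls if c.ancestrally_inactivated
        )

    @property
    def excluded_families(self) -> list[str]:
        return sorted(c.family_id for c in self.calls if c.excluded_mobile)

    def summary(self) -> str:
        lines = [
            "Ancestral gene-content reconstruction",
            f"  families examined:        {len(self.calls)}",
            f"  ancestral families:       {len(self.ancestral_families)}",
            f"  ancestrally inactivated:  {len(self.ancestrally_inactivated)}",
            f"  mobile-excluded families: {len(self.excluded_families)}",
        ]
        for lineage in sorted(self.events.lineages):
            c = self.events.counts(lineage)
            lines.append(
                f"  {lineage}: retained {c['retained']}, inactivated "
                f"{c['inactivations']}, lost {c['losses']}, acquired "
                f"{c['acquisitions']}"
            )
        if self.comparison is not None and self.comparison.valid:
            lines.append(
                f"  loss comparison {self.comparison.lineage_a} vs "
                f"{self.comparison.lineage_b}: chi2 = {self.comparison.chi2:.3f}, "
                f"df = 1, p = {self.comparison.p_value:.3g}"
            )
        return "\n".join(lines)

    def write_calls_tsv(self, path) -> None:
        with open(path, "w", newline="\n") as fh:
            fh.write(
                "family_id\tancestral\tcondition\tancestrally_inactivated\texcluded_mobile\n"
            )
            for c in sorted(self.calls, key=lambda c: c.family_id):
                fh.write(
                    f"{c.family_id}\t{str(c.ancestral).lower()}\t{c.condition}\t"
                    f"{str(c.ancestrally_inactivated).lower()}\t"
                    f"{str(c.excluded_mobile).lower()}\n"
                )
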