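"""Two-tier classification of RBP head domains into groups and subgroups.

A *group* collects head domains sharing at least 50% amino-acid identity
across at least 90% of the head window with at least one other member:
groups are the connected components (single linkage) of the thresholded
identity/coverage graph, and singleton components are reported as
"ungrouped".  Within a group, *subgroups* require at least 65% identity
between **all** subgroup members, which is exactly complete-linkage
clustering on distance 100 − identity cut at 35; subgroup letters are only
assigned when the clustering actually splits a group.

Group labels are roman numerals ordered by descending size (ties by
smallest member id); subgroup letters follow the same convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform

from .sequences import (
    HeadDomain,
    ProteinSequence,
    ScoringScheme,
    align_global,
    identity_and_coverage,
)

UNGROUPED = "ungrouped"


def _roman(n: int) -> str:
    """Roman numeral for n >= 1 (group labels I, II, III, ...)."""
    vals = [
        (1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"), (90, "XC"),
        (50, "L"), (40, "XL"), (10, "X"), (9, "IX"), (5, "V"), (4, "IV"), (1, "I"),
    ]
    out = []
    for v, s in vals:
        while n >= v:
            out.append(s)
            n -= v
    return "".join(out)


def _letters(i: int) -> str:
    """Subgroup letter for index i >= 0: A..Z, then AA, AB, ..."""
    out = ""
    i += 1
    while i:
        i, r = divmod(i - 1, 26)
        out = chr(ord("A") + r) + out
    return out


@dataclass(frozen=True)
class GroupingThresholds:
    """The identity/coverage rule set: groups at 50/90, subgroups at 65."""

    group_min_identity: float = 50.0
    group_min_coverage: float = 90.0
    subgroup_min_identity: float = 65.0

    def __post_init__(self) -> None:
        if not (0 < self.subgroup_min_identity <= 100):
            raise ValueError("subgroup_min_identity must be in (0, 100]")
        if self.group_min_identity > self.subgroup_min_identity:
            raise ValueError("group threshold must not exceed subgroup threshold")


@dataclass
class IdentityMatrix:
    """Symmetric all-vs-all percent identity and pair coverage over ids."""

    ids: list[str]
    identity: np.ndarray
    coverage: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        self.identity = np.asarray(self.identity, dtype=float)
        self.coverage = np.asarray(self.coverage, dtype=float)
        if self.identity.shape != (n, n) or self.coverage.shape != (n, n):
            raise ValueError("matrix dimensions must match ids")
        if not np.allclose(self.identity, self.identity.T):
            raise ValueError("identity matrix must be symmetric")
        if not np.allclose(self.coverage, self.coverage.T):
            raise ValueError("coverage matrix must be symmetric")
        if not np.allclose(np.diag(self.identity), 100.0):
            raise ValueError("identity diagonal must be 100")

    def index(self, seq_id: str) -> int:
        return self.ids.index(seq_id)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.identity, index=self.ids, columns=self.ids).to_csv(
            path, sep="\t", float_format="%.4f"
        )


@dataclass
class GroupAssignment:
    """Per-sequence group label (roman numeral or 'ungrouped') and subgroup letter."""

    ids: list[str]
    group: dict[str, str]  # id -> roman numeral or UNGROUPED
    subgroup: dict[str, str | None] = field(default_factory=dict)  # id -> letter or None
    # raw component index per id, before naming; retained for summaries
    component: dict[str, int] = field(default_factory=dict)

    def label(self, seq_id: str) -> str:
        g = self.group[seq_id]
        s = self.subgroup.get(seq_id)
        return g if (s is None or g == UNGROUPED) else f"{g}{s}"

    def members(self, group_label: str) -> list[str]:
        return [i for i in self.ids if self.group[i] == group_label]

    def to_frame(self, m: IdentityMatrix | None = None) -> pd.DataFrame:
        rows = []
        summary = summarize_groups(self, m) if m is not None else None
        for i in self.ids:
            g = self.group[i]
            row = {
                "sequence_id": i,
                "group": g,
                "subgroup": self.subgroup.get(i) or "",
                "n_group_members": len(self.members(g)) if g != UNGROUPED else 1,
            }
            if summary is not None:
                row["mean_within_identity"] = (
                    summary.loc[g, "mean_identity"] if g in summary.index else np.nan
                )
            rows.append(row)
        return pd.DataFrame(rows)


def build_identity_matrix(
    heads: list[HeadDomain], scheme: ScoringScheme | None = None
) -> IdentityMatrix:
    """All-against-all identity/coverage: n(n−1)/2 alignments, mirrored.

    The diagonal is filled analytically (a sequence against itself is 100/100
    by construction), matching the bidirectional all-vs-all comparison the
    grouping rule is defined over.
    """
    if not heads:
        raise ValueError("need at least one head domain")
    ids = [h.parent_id for h in heads]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate head-domain ids")
    if scheme is None:
        scheme = ScoringScheme.blosum62()
    n = len(heads)
    identity = np.full((n, n), 100.0)
    coverage = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            aln = align_global(heads[i], heads[j], scheme)
            ident, cov = identity_and_coverage(aln)
            identity[i, j] = identity[j, i] = ident
            coverage[i, j] = coverage[j, i] = cov
    return IdentityMatrix(ids=ids, identity=identity, coverage=coverage)


def _component_labels(
    m: IdentityMatrix, t: GroupingThresholds, linkage_rule: str
) -> np.ndarray:
    edges = (m.identity >= t.group_min_identity) & (m.coverage >= t.group_min_coverage)
    np.fill_diagonal(edges, False)
    if linkage_rule == "single":
        _, labels = connected_components(csr_matrix(edges), directed=False)
        return labels
    if linkage_rule == "complete":
        # complete linkage on 100 - identity, with coverage failures pushed
        # beyond any reachable distance so they can never share a cluster
        n = len(m.ids)
        if n == 1:
            return np.zeros(1, dtype=int)
        d = 100.0 - m.identity
        d[(m.coverage < t.group_min_coverage)] = 1e6
        np.fill_diagonal(d, 0.0)
        z = linkage(squareform(d, checks=False), method="complete")
        return fcluster(z, t=100.0 - t.group_min_identity, criterion="distance") - 1
    raise ValueError(f"unknown linkage rule {linkage_rule!r}")


def assign_groups(
    m: IdentityMatrix,
    t: GroupingThresholds | None = None,
    linkage_rule: str = "single",
) -> GroupAssignment:
    """Partition sequences into groups by the 50/90 identity/coverage rule.

    Components with a single member are flagged ``ungrouped`` (the published
    analysis reports one such orphan RBP, from phage 30804, that falls into
    no group).  ``linkage_rule`` defaults to single-linkage connected
    components; ``"complete"`` is available for sensitivity analysis.
    """
    if t is None:
        t = GroupingThresholds()
    labels = _component_labels(m, t, linkage_rule)
    assignment = GroupAssignment(
        ids=list(m.ids),
        group={},
        subgroup={i: None for i in m.ids},
        component={i: int(c) for i, c in zip(m.ids, labels)},
    )
    sizes = np.bincount(labels)
    for i, c in zip(m.ids, labels):
        assignment.group[i] = "" if sizes[c] >= 2 else UNGROUPED
    name_groups(assignment)
    # subgroup pass over every named (multi-member) group
    for g in sorted(set(assignment.group.values()) - {UNGROUPED}):
        members = assignment.members(g)
        letters = assign_subgroups(members, m, t)
        for seq_id, letter in letters.items():
            assignment.subgroup[seq_id] = letter
    return assignment


def assign_subgroups(
    group_ids: list[str], m: IdentityMatrix, t: GroupingThresholds | None = None
) -> dict[str, str | None]:
    """Complete-linkage subgroups at the 65% identity floor.

    Returns a letter per id when the group splits into ≥2 subgroups, else
    ``None`` for every id (undivided groups carry no letters).  Every pair
    within a returned subgroup is guaranteed identity ≥ the threshold; this
    is asserted on every run.
    """
    if t is None:
        t = GroupingThresholds()
    if len(group_ids) != len(set(group_ids)):
        raise ValueError("duplicate ids in group")
    unknown = set(group_ids) - set(m.ids)
    if unknown:
        raise ValueError(f"ids not in matrix: {sorted(unknown)}")
    if len(group_ids) <= 1:
        return {i: None for i in group_ids}
    idx = [m.index(i) for i in group_ids]
    sub = m.identity[np.ix_(idx, idx)]
    d = 100.0 - sub
    np.fill_diagonal(d, 0.0)
    z = linkage(squareform(d, checks=False), method="complete")
    clusters = fcluster(z, t=100.0 - t.subgroup_min_identity, criterion="distance")
    # guarantee the all-pairs property holds for the cut we report
    for c in np.unique(clusters):
        mask = clusters == c
        block = sub[np.ix_(mask, mask)]
        assert block.min() >= t.subgroup_min_identity - 1e-9, (
            "complete-linkage cut violated the all-pairs identity floor"
        )
    if len(np.unique(clusters)) < 2:
        return {i: None for i in group_ids}
    # letter by descending subgroup size, ties by smallest member id
    order = sorted(
        np.unique(clusters),
        key=lambda c: (-int(np.sum(clusters == c)), min(gi for gi, cl in zip(group_ids, clusters) if cl == c)),
    )
    letter_of = {c: _letters(k) for k, c in enumerate(order)}
    return {gi: letter_of[cl] for gi, cl in zip(group_ids, clusters)}


def name_groups(assignment: GroupAssignment) -> GroupAssignment:
    """Label multi-member components I, II, ... by descending size, ties by
    lexicographically smallest member id.  Deterministic in the component
    structure, independent of input order."""
    comps: dict[int, list[str]] = {}
    for i in assignment.ids:
        comps.setdefault(assignment.component[i], []).append(i)
    multi = [c for c, members in comps.items() if len(members) >= 2]
    order = sorted(multi, key=lambda c: (-len(comps[c]), min(comps[c])))
    for k, c in enumerate(order):
        label = _roman(k + 1)
        for i in comps[c]:
            assignment.group[i] = label
    for c, members in comps.items():
        if len(members) < 2:
            for i in members:
                assignment.group[i] = UNGROUPED
    return assignment


def summarize_groups(assignment: GroupAssignment, m: IdentityMatrix) -> pd.DataFrame:
    """Per-group size and min/mean/max within-group pairwise identity.

    Ungrouped sequences are excluded.  Published groups typically sit well
    above the 50% floor, in the ~82–95% identity band.
    """
    rows = []
    for g in sorted(set(assignment.group.values()) - {UNGROUPED}):
        members = assignment.members(g)
        idx = [m.index(i) for i in members]
        block = m.identity[np.ix_(idx, idx)]
        pairs = block[np.triu_indices(len(idx), k=1)]
        rows.append(
            {
                "group": g,
                "size": len(members),
                "min_identity": float(pairs.min()),
                "mean_identity": float(pairs.mean()),
                "max_identity": float(pairs.max()),
            }
        )
    return pd.DataFrame(rows).set_index("group") if rows else pd.DataFrame(
        columns=["size", "min_identity", "mean_identity", "max_identity"]
    )


def conserved_residue_report(
    heads: list[HeadDomain],
    reference: ProteinSequence,
    positions: list[int],
    scheme: ScoringScheme | None = None,
) -> pd.DataFrame:
    """Residues homologous to given 1-based reference positions, per head.

    Each head is globally aligned to the reference; for every queried
    position the residue in the homologous column is reported ('-' when the
    head is gapped there).  A position is flagged conserved when every head
    carries the reference residue.  This mirrors checking, e.g., that all
    group I heads retain the sugar-binding-crevice residues Trp 144,
    Arg 256, Asp 234 and His 232 of the phage p2 RBP.
    """
    if scheme is None:
        scheme = ScoringScheme.blosum62()
    for p in positions:
        if not (1 <= p <= len(reference)):
            raise ValueError(f"position {p} outside reference (length {len(reference)})")
    ref_head = HeadDomain(parent_id=reference.id, residues=reference.residues, offset=0)
    rows = []
    for head in heads:
        aln = align_global(head, ref_head, scheme)
        # map reference (ungapped) positions to alignment columns
        ref_pos_to_col = {}
        rp = 0
        for col, ch in enumerate(aln.aligned_b):
            if ch != "-":
                rp += 1
                ref_pos_to_col[rp] = col
        row: dict[str, object] = {"sequence_id": head.parent_id}
        for p in positions:
            row[f"pos_{p}"] = aln.aligned_a[ref_pos_to_col[p]]
        rows.append(row)
    df = pd.DataFrame(rows).set_index("sequence_id")
    conserved = {
        f"pos_{p}": bool((df[f"pos_{p}"] == reference.residues[p - 1]).all())
        for p in positions
    }
    df.attrs["conserved"] = conserved
    return df
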