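"""Synthetic data with known ground truth for every pipeline stage.

Three generators emulate the statistical structure the pipeline assumes:

* :func:`simulate_rbp_families` — protein families shaped like *Skunavirus*
  RBP head-domain groups: within-group identity in a configurable band
  (default 85–95%, matching the ~82–95% typically observed in real groups),
  optional subgroups whose cross-subgroup identity sits between the 50%
  group floor and the 65% subgroup floor, and between-group identity far
  below the group threshold.  Identity bands are enforced by measuring
  candidate sets with the package's own aligner and rejection-resampling.
* :func:`simulate_plate` — 96-well binding-assay data with no-cell control
  wells, per-well OD600, multiplicative signal and additive Gaussian noise.
* :func:`simulate_alignments` — read-to-reference alignment records with
  controlled per-read identity and aligned fraction, so filter outcomes
  (and hence abundance truth) are known exactly.

Every generator is a pure function of its spec (including the seed):
identical specs give byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .abundance import AlignmentRecord
from .binding import PlateMeasurement
from .sequences import (
    HeadDomain,
    ProteinSequence,
    ScoringScheme,
    align_global,
)

AMINO20 = "ACDEFGHIKLMNPQRSTVWY"


class BandInfeasibleError(ValueError):
    """Raised when rejection resampling cannot satisfy the identity bands."""


# ---------------------------------------------------------------------------
# RBP families


@dataclass(frozen=True)
class FamilySpec:
    """Layout and identity bands of a synthetic RBP head-domain family set.

    ``subgroup_plan`` optionally gives, per group, a list of subgroup sizes
    (overriding ``members_per_group`` for that group).  The cross-subgroup
    band must lie strictly between the 50% group floor and the 65% subgroup
    floor, otherwise planted subgroups are not recoverable by definition.
    """

    n_groups: int = 5
    members_per_group: int = 8
    subgroup_plan: dict[int, list[int]] | None = None  # group index -> sizes
    head_length: int = 110
    within_identity_band: tuple[float, float] = (85.0, 95.0)
    subgroup_cross_identity_band: tuple[float, float] = (53.0, 62.0)
    between_identity_max: float = 35.0
    n_ungrouped: int = 0
    seed: int = 0
    max_attempts: int = 1000

    def __post_init__(self) -> None:
        lo, hi = self.within_identity_band
        clo, chi = self.subgroup_cross_identity_band
        if not (self.between_identity_max < 50.0 < clo <= chi < 65.0 <= lo <= hi <= 100.0):
            raise BandInfeasibleError(
                "bands must satisfy between_max < 50 < cross band < 65 <= within band"
            )


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO20), size=length))


def _mutate(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    """Apply n point substitutions at distinct positions."""
    positions = rng.choice(len(seq), size=n_subs, replace=False)
    out = list(seq)
    for p in positions:
        alternatives = [a for a in AMINO20 if a != out[p]]
        out[p] = alternatives[rng.integers(len(alternatives))]
    return "".join(out)


def _pairwise_identity(a: str, b: str, scheme: ScoringScheme) -> float:
    aln = align_global(HeadDomain("a", a, 0), HeadDomain("b", b, 0), scheme)
    return aln.identity_pct


def _subs_for_pairwise_band(length: int, band: tuple[float, float]) -> int:
    # two members each carrying k substitutions from a shared ancestor differ
    # at ~2k positions; aim at the band centre
    target_diff = length * (1.0 - (band[0] + band[1]) / 200.0)
    return max(1, round(target_diff / 2.0))


def _subs_for_ancestor_band(
    length: int, cross_band: tuple[float, float], member_subs: int
) -> int:
    # cross-subgroup member pairs differ at ~(ancestor distance + 2k) positions;
    # ancestor distance from j substitutions each is ~2j - j^2/length
    target_diff = length * (1.0 - (cross_band[0] + cross_band[1]) / 200.0)
    anc_diff = max(2.0, target_diff - 2.0 * member_subs)
    # j substitutions per ancestor give ~2j - j^2/length differing positions
    j = anc_diff / 2.0
    j = j / (1.0 - anc_diff / (4.0 * length))  # first-order collision correction
    return max(1, round(j))


def _group_ok(
    members: list[str],
    subgroup_of: list[int],
    spec: FamilySpec,
    scheme: ScoringScheme,
) -> bool:
    lo, hi = spec.within_identity_band
    clo, chi = spec.subgroup_cross_identity_band
    for i in range(len(members)):
        for j in range(i + 1, len(members)):
            ident = _pairwise_identity(members[i], members[j], scheme)
            if subgroup_of[i] == subgroup_of[j]:
                if not (lo <= ident <= hi):
                    return False
            else:
                if not (clo <= ident <= chi):
                    return False
    return True


def _generate_group(
    rng: np.random.Generator, spec: FamilySpec, sizes: list[int], scheme: ScoringScheme
) -> tuple[list[str], list[int]]:
    k = _subs_for_pairwise_band(spec.head_length, spec.within_identity_band)
    j = _subs_for_ancestor_band(spec.head_length, spec.subgroup_cross_identity_band, k)
    for _ in range(spec.max_attempts):
        group_ancestor = _random_seq(rng, spec.head_length)
        members: list[str] = []
        subgroup_of: list[int] = []
        for sg_index, size in enumerate(sizes):
            sg_ancestor = (
                group_ancestor if len(sizes) == 1 else _mutate(rng, group_ancestor, j)
            )
            for _ in range(size):
                members.append(_mutate(rng, sg_ancestor, k))
                subgroup_of.append(sg_index)
        if _group_ok(members, subgroup_of, spec, scheme):
            return members, subgroup_of
    raise BandInfeasibleError(
        f"could not satisfy identity bands after {spec.max_attempts} attempts"
    )


def simulate_rbp_families(
    spec: FamilySpec, scheme: ScoringScheme | None = None
) -> tuple[list[ProteinSequence], pd.DataFrame]:
    """Generate head-domain families plus a truth-label table.

    Returns sequences (ids ``rbp001`` ...) and a DataFrame with columns
    ``sequence_id``, ``true_group`` (``g1`` ... or ``ungrouped``) and
    ``true_subgroup`` (``g1.1`` ... or empty).
    """
    if scheme is None:
        scheme = ScoringScheme.blosum62()
    rng = np.random.default_rng(spec.seed)
    groups: list[tuple[list[str], list[int]]] = []
    for g in range(spec.n_groups):
        sizes = (
            spec.subgroup_plan.get(g, [spec.members_per_group])
            if spec.subgroup_plan
            else [spec.members_per_group]
        )
        groups.append(_generate_group(rng, spec, sizes, scheme))

    # ungrouped singletons: independent random sequences
    singles: list[str] = [_random_seq(rng, spec.head_length) for _ in range(spec.n_ungrouped)]

    # verify separation: every cross-group / singleton identity below the cap
    pools: list[list[str]] = [m for m, _ in groups] + [[s] for s in singles]
    for _ in range(spec.max_attempts):
        violation = None
        for a in range(len(pools)):
            for b in range(a + 1, len(pools)):
                for sa in pools[a]:
                    for sb in pools[b]:
                        if _pairwise_identity(sa, sb, scheme) > spec.between_identity_max:
                            violation = b
                            break
                    if violation is not None:
                        break
                if violation is not None:
                    break
            if violation is not None:
                break
        if violation is None:
            break
        # redraw the offending pool
        if violation >= len(groups):
            pools[violation] = [_random_seq(rng, spec.head_length)]
        else:
            sizes = (
                spec.subgroup_plan.get(violation, [spec.members_per_group])
                if spec.subgroup_plan
                else [spec.members_per_group]
            )
            members, subgroup_of = _generate_group(rng, spec, sizes, scheme)
            pools[violation] = members
            groups[violation] = (members, subgroup_of)
    else:
        raise BandInfeasibleError("could not separate groups below between_identity_max")

    seqs: list[ProteinSequence] = []
    rows = []
    idx = 0
    for g, (members, subgroup_of) in enumerate(groups):
        n_subgroups = len(set(subgroup_of))
        for member, sg in zip(members, subgroup_of):
            idx += 1
            seq_id = f"rbp{idx:03d}"
            seqs.append(ProteinSequence(id=seq_id, residues=member))
            rows.append(
                {
                    "sequence_id": seq_id,
                    "true_group": f"g{g + 1}",
                    "true_subgroup": f"g{g + 1}.{sg + 1}" if n_subgroups > 1 else "",
                }
            )
    for s in singles:
        idx += 1
        seq_id = f"rbp{idx:03d}"
        seqs.append(ProteinSequence(id=seq_id, residues=s))
        rows.append({"sequence_id": seq_id, "true_group": "ungrouped", "true_subgroup": ""})
    return seqs, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Binding-assay plates


@dataclass(frozen=True)
class PlateSpec:
    """A simulated binding-assay plate.

    ``true_affinity`` rows are RBPs, columns strains, entries in [0, 1].
    Sample wells read ``background + od · signal_gain · affinity`` plus
    Gaussian noise with standard deviation ``noise_sd_fraction`` of the
    signal term; control wells read ``background`` plus noise at the same
    fraction of the background.  OD600 is uniform over ``od_range``,
    emulating cultures harvested at mid-log phase (~0.4–0.7).
    """

    true_affinity: pd.DataFrame
    signal_gain: float = 3.0e5
    background: float = 500.0
    noise_sd_fraction: float = 0.05
    od_range: tuple[float, float] = (0.4, 0.7)
    replicates: int = 3
    n_controls: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        a = self.true_affinity.to_numpy(dtype=float)
        if (a < 0).any() or (a > 1).any():
            raise ValueError("affinities must be in [0, 1]")
        if self.noise_sd_fraction < 0:
            raise ValueError("noise_sd_fraction must be >= 0")


def true_relative_scores(spec: PlateSpec) -> pd.DataFrame:
    """Ground-truth relative scores: 100 · affinity / row max (NaN rows all-zero)."""
    a = spec.true_affinity
    row_max = a.max(axis=1)
    scores = 100.0 * a.div(row_max.replace(0, np.nan), axis=0)
    return scores


def simulate_plate(spec: PlateSpec) -> tuple[list[PlateMeasurement], pd.DataFrame]:
    """Generate plate wells plus the ground-truth relative-score table."""
    rng = np.random.default_rng(spec.seed)
    wells: list[PlateMeasurement] = []
    for rbp in spec.true_affinity.index:
        for rep in range(1, spec.n_controls + 1):
            raw = spec.background + rng.normal(0.0, spec.noise_sd_fraction * spec.background)
            wells.append(
                PlateMeasurement(
                    rbp_id=str(rbp),
                    replicate=rep,
                    raw_fluorescence=max(0.0, raw),
                    is_control=True,
                )
            )
        for strain in spec.true_affinity.columns:
            affinity = float(spec.true_affinity.loc[rbp, strain])
            for rep in range(1, spec.replicates + 1):
                od = rng.uniform(*spec.od_range)
                signal = od * spec.signal_gain * affinity
                raw = spec.background + signal + rng.normal(
                    0.0, spec.noise_sd_fraction * signal
                )
                wells.append(
                    PlateMeasurement(
                        rbp_id=str(rbp),
                        strain_id=str(strain),
                        replicate=rep,
                        raw_fluorescence=max(0.0, raw),
                        od600=od,
                    )
                )
    return wells, true_relative_scores(spec)


# ---------------------------------------------------------------------------
# Read alignments


@dataclass(frozen=True)
class IdentityMixture:
    """Per-read identity / aligned-fraction mixture around the filter thresholds.

    With probability ``pass_fraction`` a read draws both quantities from the
    passing ranges; otherwise its identity comes from the failing range (so
    the expected filter pass rate among mapped reads equals
    ``pass_fraction``).  Default ranges bracket the contig-mode 86/95
    thresholds with a 2-point safety margin against integer rounding of
    edit distances and aligned lengths.
    """

    pass_fraction: float = 0.9
    pass_identity_range: tuple[float, float] = (90.0, 100.0)
    fail_identity_range: tuple[float, float] = (60.0, 82.0)
    pass_aligned_range: tuple[float, float] = (97.0, 100.0)
    fail_aligned_range: tuple[float, float] = (50.0, 90.0)

    def __post_init__(self) -> None:
        if not (0 <= self.pass_fraction <= 1):
            raise ValueError("pass_fraction must be in [0, 1]")


@dataclass(frozen=True)
class ReadSimSpec:
    """A simulated read-mapping corpus with known category weights.

    ``refs`` maps reference id to (length_bp, category); ``true_weights``
    are category proportions summing to 1.  A read first draws its category
    from ``true_weights``, then a reference within the category with
    probability proportional to length, then a start position uniformly.
    """

    refs: dict[str, tuple[int, str]]
    true_weights: dict[str, float]
    n_reads: int = 10000
    read_length: int = 150
    identity_mixture: IdentityMixture = field(default_factory=IdentityMixture)
    unmapped_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.true_weights.values()) - 1.0) > 1e-9:
            raise ValueError("true_weights must sum to 1")
        if not (0 <= self.unmapped_fraction <= 1):
            raise ValueError("unmapped_fraction must be in [0, 1]")
        cats = {c for _, c in self.refs.values()}
        if set(self.true_weights) != cats:
            raise ValueError("true_weights keys must match reference categories")


def simulate_alignments(
    spec: ReadSimSpec,
) -> tuple[list[AlignmentRecord], pd.DataFrame]:
    """Generate alignment records plus a truth table of category weights."""
    rng = np.random.default_rng(spec.seed)
    categories = sorted(spec.true_weights)
    cat_probs = np.array([spec.true_weights[c] for c in categories])
    refs_by_cat = {
        c: sorted(r for r, (_, rc) in spec.refs.items() if rc == c) for c in categories
    }
    len_probs = {
        c: np.array([spec.refs[r][0] for r in refs_by_cat[c]], dtype=float)
        for c in categories
    }
    for c in categories:
        len_probs[c] = len_probs[c] / len_probs[c].sum()

    mix = spec.identity_mixture
    records: list[AlignmentRecord] = []
    for i in range(spec.n_reads):
        read_id = f"read{i + 1:06d}"
        if rng.random() < spec.unmapped_fraction:
            records.append(AlignmentRecord(read_id=read_id, ref_id=None))
            continue
        cat = categories[rng.choice(len(categories), p=cat_probs)]
        ref = refs_by_cat[cat][rng.choice(len(refs_by_cat[cat]), p=len_probs[cat])]
        ref_len = spec.refs[ref][0]
        passes = rng.random() < mix.pass_fraction
        if passes:
            identity = rng.uniform(*mix.pass_identity_range)
            aligned_pct = rng.uniform(*mix.pass_aligned_range)
        else:
            identity = rng.uniform(*mix.fail_identity_range)
            aligned_pct = rng.uniform(*mix.pass_aligned_range)
        aligned_len = max(1, round(spec.read_length * aligned_pct / 100.0))
        aligned_len = min(aligned_len, spec.read_length, ref_len)
        start = int(rng.integers(1, max(1, ref_len - aligned_len + 1) + 1))
        nm = round(aligned_len * (1.0 - identity / 100.0))
        records.append(
            AlignmentRecord(
                read_id=read_id,
                ref_id=ref,
                ref_start=start,
                aligned_length=aligned_len,
                read_length=spec.read_length,
                percent_identity=100.0 * (aligned_len - nm) / aligned_len,
                ref_aligned_length=aligned_len,
            )
        )
    truth = pd.DataFrame(
        {
            "category": categories,
            "true_weight": [spec.true_weights[c] for c in categories],
        }
    )
    truth.attrs["unmapped_fraction"] = spec.unmapped_fraction
    truth.attrs["pass_fraction"] = mix.pass_fraction
    return records, truth


def write_sam(
    records: list[AlignmentRecord], refs: dict[str, tuple[int, str]], path: str | Path
) -> None:
    """Write records as plain headerful SAM (soft-clipped tails, NM tags)."""
    with open(path, "w") as handle:
        handle.write("@HD\tVN:1.6\tSO:unsorted\n")
        for ref in sorted(refs):
            handle.write(f"@SQ\tSN:{ref}\tLN:{refs[ref][0]}\n")
        for rec in records:
            if not rec.mapped:
                handle.write(
                    f"{rec.read_id}\t4\t*\t0\t0\t*\t*\t0\t0\t*\t*\n"
                )
                continue
            clip = rec.read_length - rec.aligned_length
            cigar = f"{rec.aligned_length}M" + (f"{clip}S" if clip else "")
            nm = round(rec.aligned_length * (1.0 - rec.percent_identity / 100.0))
            handle.write(
                f"{rec.read_id}\t0\t{rec.ref_id}\t{rec.ref_start}\t60\t{cigar}"
                f"\t*\t0\t0\t*\t*\tNM:i:{nm}\n"
            )
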