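"""Chromosome-scale phasing and crossover-breakpoint inference.

Gamete codes are labelled a/b per marker with an arbitrary polarity; the
pairwise linkage phase (coupling/repulsion) lets that polarity be propagated
along a mapped linkage group so that "a" denotes one consistent haplotype
end to end.  The resulting phased parent (two allele strings per LG) is the
reference against which a transmitted gamete — the donor gamete inside a
hybrid, or a haploid derivative genotyped directly — is decomposed into
haplotype blocks.  Transitions between blocks are crossover breakpoints,
reported as the interval between the flanking informative markers (the data
never localize a crossover more finely than that).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._util import CODE_MISSING
from .linkage import estimate_rf
from .ordering import GeneticMap, LinkageGroup
from .segcoding import MISSING_CALL, NULL, DataIntegrityError, GameteMatrix, observed_call

__all__ = [
    "PhasedLG",
    "PhasedParent",
    "BlockReport",
    "BreakpointReport",
    "phase_parent",
    "phase_map",
    "infer_donor_allele",
    "assign_blocks",
    "donor_breakpoints",
    "analyze_haploid",
]


@dataclass
class PhasedLG:
    """Phase-resolved haplotypes of one parent on one linkage group."""

    lg_id: str
    markers: list[str]
    positions: np.ndarray
    flips: np.ndarray  # bool: True where original code "b" belongs to h1
    h1: list[str]  # allele of haplotype 1 per marker
    h2: list[str]
    conflicts: list[str] = field(default_factory=list)

    def aligned_codes(self, gam: GameteMatrix) -> np.ndarray:
        """Gamete codes re-labelled so 0 = haplotype 1 throughout the LG."""
        rows = [gam.markers.index(m) for m in self.markers]
        codes = gam.codes[rows].copy()
        flip = self.flips[:, None] & (codes != CODE_MISSING)
        codes[flip] = 1 - codes[flip]
        return codes


@dataclass
class PhasedParent:
    parent: str
    lgs: dict[str, PhasedLG]

    def lg(self, lg_id: str) -> PhasedLG:
        return self.lgs[lg_id]


def phase_parent(gam: GameteMatrix, lg: LinkageGroup, look_back: int = 3) -> PhasedLG:
    """Propagate pairwise phase along the map order of one linkage group.

    The first marker anchors the frame (flip = False).  Each subsequent
    marker is oriented by majority vote over its pairwise phase with up to
    ``look_back`` preceding markers; an inconsistent vote is resolved by the
    majority and logged as a conflict.
    """
    markers = [m for m in lg.markers if m in gam.markers]
    positions = np.array([lg.position_of(m) for m in markers])
    rows = {m: gam.markers.index(m) for m in markers}
    k = len(markers)
    flips = np.zeros(k, dtype=bool)
    conflicts: list[str] = []
    for i in range(1, k):
        votes = []
        for j in range(max(0, i - look_back), i):
            pl = estimate_rf(gam.codes[rows[markers[j]]], gam.codes[rows[markers[i]]])
            if pl is None or pl.ind_lod <= 0:
                continue
            repulsion = pl.phase == "repulsion"
            votes.append(bool(flips[j]) ^ repulsion)
        if not votes:
            flips[i] = flips[i - 1]
            conflicts.append(f"{markers[i]}: unphased (no informative pair)")
            continue
        n_true = sum(votes)
        flips[i] = n_true * 2 > len(votes) or (n_true * 2 == len(votes) and votes[-1])
        if 0 < n_true < len(votes):
            conflicts.append(f"{markers[i]}: phase votes disagree ({n_true}/{len(votes)})")
    h1, h2 = [], []
    for m, fl in zip(markers, flips):
        a0, a1 = gam.allele_of_code.get(m, ("a", "b"))
        h1.append(a1 if fl else a0)
        h2.append(a0 if fl else a1)
    return PhasedLG(lg.lg_id, markers, positions, flips, h1, h2, conflicts)


def phase_map(gam: GameteMatrix, gmap: GeneticMap, look_back: int = 3) -> PhasedParent:
    """Phase every linkage group of a parent's map."""
    return PhasedParent(gam.parent, {lg.lg_id: phase_parent(gam, lg, look_back)
                                     for lg in gmap.linkage_groups})


def infer_donor_allele(hybrid_call: str, nondonor_genotype: str) -> str | None:
    """Allele the donor parent transmitted to a hybrid, or None.

    ``nondonor_genotype`` is the (resolved) genotype of the other parent and
    may contain a null allele.  A donor allele is returned only when every
    gamete combination consistent with the hybrid's call implies the same
    one; a null donor candidate is discarded when a visible allele also
    fits.  Raises :class:`DataIntegrityError` when no combination explains
    the call (the hybrid carries an allele it could not have inherited).
    """
    if hybrid_call in (MISSING_CALL, None) or nondonor_genotype in (MISSING_CALL, None):
        return None
    alleles = set("ABCD") | {NULL}
    cands = set()
    for x in set(nondonor_genotype):
        for y in alleles:
            if observed_call(x + y) == hybrid_call:
                cands.add(y)
    if not cands:
        raise DataIntegrityError(
            f"hybrid call {hybrid_call!r} impossible with non-donor {nondonor_genotype!r}"
        )
    visible = cands - {NULL}
    if len(visible) == 1:
        return next(iter(visible))
    if not visible and len(cands) == 1:
        return next(iter(cands))
    return None


@dataclass
class BlockReport:
    """Donor-haplotype decomposition of one linkage group."""

    lg_id: str
    markers: list[str]
    assignments: list[str]  # h1 | h2 | uninformative | conflict
    blocks: list[tuple[str, str, str]]  # (label, first marker, last marker)
    breakpoints: list[tuple[str, str, float, float]]  # flanks + cM bounds
    unassignable: bool = False

    @property
    def n_breakpoints(self) -> int:
        return len(self.breakpoints)


@dataclass
class BreakpointReport:
    per_lg: dict[str, BlockReport]

    @property
    def total_breakpoints(self) -> int:
        return sum(b.n_breakpoints for b in self.per_lg.values())

    def counts(self) -> dict[str, int]:
        return {lg: b.n_breakpoints for lg, b in self.per_lg.items()}


def assign_blocks(
    donor_alleles: list[str | None],
    phased: PhasedLG,
    min_support: int = 2,
) -> BlockReport:
    """Assign donor alleles to the donor's haplotypes and call breakpoints.

    Markers where the phased donor is heterozygous and a donor allele is
    known are assigned h1/h2 by allele match.  Runs of fewer than
    ``min_support`` consecutive informative assignments are relabelled
    "conflict" (treated as genotyping error) before blocks are merged;
    breakpoints lie between adjacent opposite-assignment informative
    markers and are reported with the flanking markers' cM positions.
    """
    k = len(phased.markers)
    assert len(donor_alleles) == k
    assignments = ["uninformative"] * k
    for i in range(k):
        al = donor_alleles[i]
        if al is None or phased.h1[i] == phased.h2[i]:
            continue
        if al == phased.h1[i]:
            assignments[i] = "h1"
        elif al == phased.h2[i]:
            assignments[i] = "h2"
        else:
            assignments[i] = "conflict"
    info_idx = [i for i in range(k) if assignments[i] in ("h1", "h2")]
    if not info_idx:
        return BlockReport(phased.lg_id, list(phased.markers), assignments, [], [],
                           unassignable=True)
    # runs over consecutive informative assignments
    runs: list[list[int]] = [[info_idx[0]]]
    for i in info_idx[1:]:
        if assignments[i] == assignments[runs[-1][-1]]:
            runs[-1].append(i)
        else:
            runs.append([i])
    for run in runs:
        if len(run) < min_support:
            for i in run:
                assignments[i] = "conflict"
    kept = [i for i in info_idx if assignments[i] in ("h1", "h2")]
    if not kept:
        return BlockReport(phased.lg_id, list(phased.markers), assignments, [], [],
                           unassignable=True)
    blocks: list[list[int]] = [[kept[0]]]
    for i in kept[1:]:
        if assignments[i] == assignments[blocks[-1][-1]]:
            blocks[-1].append(i)
        else:
            blocks.append([i])
    block_list = [
        (assignments[b[0]], phased.markers[b[0]], phased.markers[b[-1]]) for b in blocks
    ]
    breakpoints = []
    for left, right in zip(blocks[:-1], blocks[1:]):
        i, j = left[-1], right[0]
        breakpoints.append(
            (phased.markers[i], phased.markers[j],
             float(phased.positions[i]), float(phased.positions[j]))
        )
    return BlockReport(phased.lg_id, list(phased.markers), assignments, block_list,
                       breakpoints)


def donor_breakpoints(
    hybrid_calls,
    nondonor_genotypes,
    phased: PhasedParent,
    min_support: int = 2,
) -> tuple[BreakpointReport, list[str]]:
    """Decompose a hybrid's donor-derived haplotype against the donor's phases.

    ``hybrid_calls`` and ``nondonor_genotypes`` map marker -> call/genotype.
    Markers whose calls are incompatible with the non-donor parent are
    dropped and reported.
    """
    per_lg = {}
    dropped: list[str] = []
    for lg_id, plg in phased.lgs.items():
        alleles: list[str | None] = []
        for m in plg.markers:
            try:
                alleles.append(
                    infer_donor_allele(hybrid_calls.get(m), nondonor_genotypes.get(m))
                )
            except DataIntegrityError:
                dropped.append(m)
                alleles.append(None)
        per_lg[lg_id] = assign_blocks(alleles, plg, min_support)
    return BreakpointReport(per_lg), dropped


def analyze_haploid(
    haploid_calls,
    phased: PhasedParent,
    min_support: int = 2,
):
    """Breakpoints of the gamete that produced a haploid derivative.

    ``haploid_calls`` maps marker -> single-allele call (missing allowed).
    Returns the breakpoint report and a per-LG origin summary (fraction of
    informative markers from each source haplotype, and whether the LG was
    inherited without recombination).
    """
    import pandas as pd

    per_lg = {}
    for lg_id, plg in phased.lgs.items():
        alleles: list[str | None] = []
        for m in plg.markers:
            v = haploid_calls.get(m)
            if v in (None, MISSING_CALL, NULL):
                alleles.append(None)
                continue
            v = str(v)
            if len(v) > 1 and v[0] != v[1]:
                raise DataIntegrityError(f"{m}: heterozygous call {v!r} in haploid input")
            alleles.append(v[0])
        per_lg[lg_id] = assign_blocks(alleles, plg, min_support)
    report = BreakpointReport(per_lg)
    rows = []
    for lg_id, blk in report.per_lg.items():
        n1 = blk.assignments.count("h1")
        n2 = blk.assignments.count("h2")
        tot = n1 + n2
        rows.append(
            {
                "lg": lg_id,
                "n_informative": tot,
                "frac_h1": n1 / tot if tot else np.nan,
                "frac_h2": n2 / tot if tot else np.nan,
                "n_breakpoints": blk.n_breakpoints,
                "unrecombined": blk.n_breakpoints == 0 and tot > 0,
            }
        )
    return report, pd.DataFrame(rows).set_index("lg")
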