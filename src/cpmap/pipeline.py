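"""End-to-end orchestration: from gamete matrices to cleaned genetic maps,
and from a study-like simulated dataset to the full analysis.

``build_parent_map`` is the canonical per-parent pipeline: two-point table,
independence-LOD grouping, regression ordering per group, chromosome-scale
phasing, singleton detection, one cleaning round, and a final remap with
distortion statistics attached.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import distortion as dist
from . import haplotypes as hap
from .linkage import MarkerGroupSet, group_markers, pairwise_table
from .ordering import (
    GeneticMap,
    LinkageGroup,
    SingletonReport,
    clean_and_remap,
    detect_singletons,
    order_markers_regression,
    summarize_map,
)
from .segcoding import GameteMatrix

__all__ = ["MapResult", "build_parent_map", "run_study_analysis"]


@dataclass
class MapResult:
    """Everything produced while mapping one parent (or joined dataset)."""

    genetic_map: GeneticMap
    gametes: GameteMatrix  # singleton-cleaned codes (original polarity)
    groups: MarkerGroupSet
    phased: hap.PhasedParent
    distortion: pd.DataFrame
    singletons: SingletonReport
    summary: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def total_length(self) -> float:
        return self.genetic_map.total_length


def _name_groups(
    lgs: list[tuple[list[str], LinkageGroup]], anchor_table: dict[str, str] | None
) -> list[LinkageGroup]:
    """Assign LG ids: by anchor-table majority when available, else by size."""
    named: list[LinkageGroup] = []
    if anchor_table:
        used: dict[str, int] = {}
        for members, lg in sorted(lgs, key=lambda t: -len(t[0])):
            votes = pd.Series([anchor_table[m] for m in members if m in anchor_table])
            if len(votes):
                name = votes.value_counts().idxmax()
                if name in used:
                    used[name] += 1
                    name = f"{name}.{used[name]}"
                else:
                    used[name] = 1
            else:
                name = f"U{len(named) + 1}"
            lg.lg_id = name
            named.append(lg)
    else:
        for i, (_, lg) in enumerate(sorted(lgs, key=lambda t: -len(t[0])), start=1):
            lg.lg_id = f"LG{i}"
            named.append(lg)
    named.sort(key=lambda g: g.lg_id)
    return named


def build_parent_map(
    gam: GameteMatrix,
    lod_threshold: float = 4.0,
    anchor_table: dict[str, str] | None = None,
    clean_singletons: bool = True,
    alpha: float = 0.05,
    **order_kwargs,
) -> MapResult:
    """Group, order, phase and clean one parent's gamete matrix."""
    pairs = pairwise_table(gam.codes, gam.markers)
    groups = group_markers(pairs, gam.markers, lod_threshold)
    raw_lgs: list[tuple[list[str], LinkageGroup]] = []
    for members in groups.groups:
        rows = [gam.markers.index(m) for m in members]
        lg = order_markers_regression(
            members, gam.codes[rows], pairs, lg_id="tmp", **order_kwargs
        )
        raw_lgs.append((members, lg))
    lgs = _name_groups(raw_lgs, anchor_table)

    all_cells = []
    final_lgs: list[LinkageGroup] = []
    clean_codes = gam.codes.copy()
    row_of = {m: i for i, m in enumerate(gam.markers)}
    if clean_singletons:
        for lg in lgs:
            plg = hap.phase_parent(gam, lg)
            aligned = plg.aligned_codes(gam)
            rep = detect_singletons(lg, plg.markers, aligned, gam.individuals)
            all_cells.extend(rep.cells)
            if rep.cells:
                rows = [row_of[m] for m in lg.markers]
                sub_codes = gam.codes[rows]
                cleaned_sub, new_lg = clean_and_remap(
                    lg.markers, sub_codes, gam.individuals, lg, rep, **order_kwargs
                )
                for r, m in enumerate(lg.markers):
                    clean_codes[row_of[m]] = cleaned_sub[r]
                new_lg.lg_id = lg.lg_id
                final_lgs.append(new_lg)
            else:
                final_lgs.append(lg)
    else:
        final_lgs = lgs
    report = SingletonReport(all_cells, {})
    for lg in final_lgs:
        report.per_lg[lg.lg_id] = sum(1 for m, _ in all_cells if m in set(lg.markers))

    gam_clean = GameteMatrix(gam.parent, list(gam.markers), list(gam.individuals),
                             clean_codes, dict(gam.allele_of_code))
    gmap = GeneticMap(gam.parent, final_lgs)
    phased = hap.phase_map(gam_clean, gmap)
    records = dist.scan_gametes(gam_clean, alpha)
    summary = summarize_map(gmap, records["p"] if len(records) else None, alpha)
    return MapResult(gmap, gam_clean, groups, phased, records, report, summary)


# ---------------------------------------------------------------------------
# full study-like analysis


def run_study_analysis(
    seed: int = 1,
    scale: float = 0.25,
    error_rate: float = 0.002,
    missing_rate: float = 0.03,
    lod_threshold: float = 4.0,
    min_support: int = 2,
    alpha: float = 0.05,
) -> dict:
    """Simulate the three-progeny study design and run the whole analysis.

    Returns a dictionary with the dataset, per-parent map results, the
    joined reference map of the central parent, distortion summaries,
    fixation-index tables and the donor/haploid breakpoint reports.
    """
    from . import mapcompare as mc
    from .segcoding import census_segregation_types, code_markers, derive_gamete_matrix
    from .simdata import make_study_like_dataset

    ds = make_study_like_dataset(seed, scale=scale, error_rate=error_rate,
                                 missing_rate=missing_rate)
    anchor = ds.truemap.marker_info["lg"].to_dict()
    out: dict = {"dataset": ds, "maps": {}, "configs": {}, "census": {},
                 "fixation": {}}

    plan = [  # (bundle, parent slot, label)
        ("CPxNC", 1, "CH"), ("CPxNC", 2, "CL_male"),
        ("NCxPP", 1, "CL_female"), ("NCxPP", 2, "PK"),
        ("SOxTO", 1, "SO"),
    ]
    gams: dict[str, GameteMatrix] = {}
    rng = np.random.default_rng(seed + 101)
    for name in ("CPxNC", "NCxPP", "SOxTO"):
        b = ds.bundle(name)
        configs = code_markers(b.genotypes)
        out["configs"][name] = configs
        out["census"][name] = census_segregation_types(configs)
        out["fixation"][name] = dist.fixation_index(b.genotypes, configs, rng=rng)
    for name, slot, label in plan:
        b = ds.bundle(name)
        gams[label] = derive_gamete_matrix(b.genotypes, out["configs"][name], slot,
                                           label=label)
        out["maps"][label] = build_parent_map(
            gams[label], lod_threshold, anchor_table=anchor, alpha=alpha
        )
    out["gametes"] = gams

    # joined reference map of the central parent
    joined = mc.join_parent_datasets(gams["CL_male"], gams["CL_female"], label="CL_joined")
    out["maps"]["CL_joined"] = build_parent_map(joined, lod_threshold,
                                                anchor_table=anchor, alpha=alpha)

    # skewed fractions per parent map
    out["skew"] = {
        label: dist.skewed_fraction(res.genetic_map, res.distortion, alpha)
        for label, res in out["maps"].items()
    }

    # donor-gamete breakpoints: central parent's calls against the donor's phases
    so_res = out["maps"]["SO"]
    report, dropped = hap.donor_breakpoints(
        ds.central_calls.to_dict(),
        {m: ds.nondonor_calls[m] for m in ds.nondonor_calls.index},
        so_res.phased, min_support=min_support,
    )
    out["donor_breakpoints"] = report
    out["donor_dropped_markers"] = dropped

    # haploid derivative against the central parent's joined phases
    hrep, hsum = hap.analyze_haploid(ds.haploid_calls.to_dict(),
                                     out["maps"]["CL_joined"].phased,
                                     min_support=min_support)
    out["haploid_breakpoints"] = hrep
    out["haploid_summary"] = hsum

    # ancestral-allele (seed-parent) origin excess along the central parent maps
    origin = {}
    for m in ds.central_calls.index:
        try:
            donor_allele = hap.infer_donor_allele(ds.central_calls[m],
                                                  ds.nondonor_calls[m])
        except Exception:
            continue
        if donor_allele is None:
            continue
        cl = ds.central_calls[m]
        anc = cl[0] if cl[1] == donor_allele else (cl[1] if cl[0] == donor_allele else None)
        if anc is None:
            continue
        origin[m] = anc
    for label in ("CL_male", "CL_female"):
        gam = out["maps"][label].gametes
        table = {}
        for m, anc in origin.items():
            pair = gam.allele_of_code.get(m)
            if pair and anc in pair:
                table[m] = pair.index(anc)
        out[f"origin_excess_{label}"], _ = dist.allele_origin_excess(gam, table, alpha)

    # cross-parent comparisons on shared mapped markers
    cl_map = out["maps"]["CL_joined"].genetic_map
    so_map = so_res.genetic_map
    shared = [m for lg in cl_map.linkage_groups for m in lg.markers
              if any(m in lg2.markers for lg2 in so_map.linkage_groups)]
    out["colinearity_CL_SO"] = mc.colinearity_stats(cl_map, so_map)
    if shared:
        _, lengths = mc.common_marker_remap(
            {"CL": out["maps"]["CL_joined"].gametes, "SO": so_res.gametes},
            shared, anchor_table=anchor, lod_threshold=lod_threshold,
        )
        out["shared_marker_lengths"] = lengths
    out["projection_SO_into_CL"] = mc.project_markers(so_map, cl_map)
    return out
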