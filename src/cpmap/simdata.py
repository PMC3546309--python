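"""Meiosis and progeny simulator for outbred F1 mapping designs.

The simulator draws gametes from phased parents under a stationary renewal
crossover process — a gamma model whose shape parameter ``nu`` controls
crossover interference (``nu = 1`` is the no-interference Poisson/Haldane
case; the default ``nu = 2.63`` closely matches the Kosambi map function
used by the estimation side).  Chiasmata occur on the four-strand bundle at
rate 2 per Morgan and each involves a given chromatid with probability 1/2,
so the per-gamete crossover density is 1 per Morgan.

Gametic selection is modelled by rejection sampling on whole gametes
(pollen competition / gamete abortion): a gamete is retained with
probability prod over selected loci of (1 if it carries the favored
haplotype else 1 - s).  At a selected locus the favored-haplotype frequency
among accepted gametes converges to 1/(2-s).  A zygotic variant (killing
heterozygous zygotes) is provided for the fixation-index contrast.

``make_study_like_dataset`` assembles three progeny sets with the structure
of a citrus-style design: two crosses sharing one central heterozygous
parent (mapped as male in one cross, n = 156, and as female in the other,
n = 140) and a third cross (n = 147) mapping one of the central parent's own
ancestors, whose donor gamete carries a configurable crossover layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .segcoding import (
    MISSING_CALL,
    NULL,
    GenotypeMatrix,
    canonical_genotype,
    observed_call,
)

__all__ = [
    "TrueMap",
    "TrueLG",
    "SelectedLocus",
    "SelectionModel",
    "SimConfig",
    "GameteBatch",
    "SimTruth",
    "StudyBundle",
    "StudyDataset",
    "ConfigurationError",
    "SimulationError",
    "simulate_crossovers",
    "simulate_gametes",
    "simulate_gamete",
    "gamete_with_layout",
    "apply_gametic_selection",
    "genotype_progeny",
    "simulate_progeny",
    "make_study_like_dataset",
]


class ConfigurationError(ValueError):
    """Bad simulator configuration (unknown model name, invalid rate...)."""


class SimulationError(RuntimeError):
    """Simulation cannot proceed (e.g. selection exhausts the gamete pool)."""


@dataclass
class TrueLG:
    lg_id: str
    markers: list[str]
    positions: np.ndarray  # strictly increasing cM

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if np.any(np.diff(self.positions) <= 0):
            raise ConfigurationError(f"{self.lg_id}: positions must be strictly increasing")

    @property
    def length(self) -> float:
        return float(self.positions[-1]) if len(self.markers) else 0.0


@dataclass
class TrueMap:
    """Ground-truth map: LG structure plus phased parental alleles.

    ``marker_info`` is indexed by marker with columns ``lg``, ``pos``,
    ``marker_class`` and phased alleles ``p1_h1, p1_h2, p2_h1, p2_h2``
    over the symbols {A, B, C, D, 0}.
    """

    lgs: list[TrueLG]
    marker_info: pd.DataFrame

    def __post_init__(self):
        allowed = set("ABCD0")
        for col in ("p1_h1", "p1_h2", "p2_h1", "p2_h2"):
            bad = set(self.marker_info[col].unique()) - allowed
            if bad:
                raise ConfigurationError(f"illegal allele symbols {bad} in {col}")

    @property
    def markers(self) -> list[str]:
        return [m for lg in self.lgs for m in lg.markers]

    def lg(self, lg_id: str) -> TrueLG:
        for g in self.lgs:
            if g.lg_id == lg_id:
                return g
        raise KeyError(lg_id)

    def parent_genotype(self, parent: int, marker: str) -> str:
        row = self.marker_info.loc[marker]
        h1, h2 = (row["p1_h1"], row["p1_h2"]) if parent == 1 else (row["p2_h1"], row["p2_h2"])
        return canonical_genotype(h1 + h2)


@dataclass(frozen=True)
class SelectedLocus:
    lg_id: str
    pos_cM: float
    sex: str  # "male" | "female" | "both"
    favored_hap: int  # 0 or 1: haplotype index of the affected parent
    s: float

    def __post_init__(self):
        if not (0.0 <= self.s <= 1.0):
            raise ConfigurationError("selection coefficient must lie in [0, 1]")
        if self.sex not in ("male", "female", "both"):
            raise ConfigurationError(f"unknown sex {self.sex!r}")


@dataclass
class SelectionModel:
    loci: list[SelectedLocus] = field(default_factory=list)

    def for_sex(self, sex: str) -> list[SelectedLocus]:
        return [l for l in self.loci if l.sex in (sex, "both")]


@dataclass
class SimConfig:
    n_progeny: int = 150
    interference_model: str = "gamma"  # "gamma" | "poisson"
    nu: float = 2.63
    genotyping_error_rate: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.interference_model not in ("gamma", "poisson"):
            raise ConfigurationError(
                f"unknown interference model {self.interference_model!r}"
            )
        for r in (self.genotyping_error_rate, self.missing_rate):
            if not (0.0 <= r <= 1.0):
                raise ConfigurationError("rates must lie in [0, 1]")


# ---------------------------------------------------------------------------
# crossover process


def simulate_crossovers(
    length_cM: float, n: int, model: str = "gamma", nu: float = 2.63, rng=None
) -> list[np.ndarray]:
    """Crossover positions (cM) for ``n`` gametes on one chromosome.

    gamma: stationary gamma renewal chiasma process on the bundle (shape
    ``nu``, intensity 2/Morgan) thinned by 1/2 per chromatid; stationarity is
    obtained by starting the renewal process 5 Morgans before the chromosome.
    poisson: crossover count ~ Poisson(L Morgans), positions uniform.
    """
    rng = np.random.default_rng(rng)
    if model == "poisson":
        counts = rng.poisson(length_cM / 100.0, size=n)
        return [np.sort(rng.uniform(0.0, length_cM, size=int(c))) for c in counts]
    if model != "gamma":
        raise ConfigurationError(f"unknown interference model {model!r}")
    L = length_cM / 100.0
    if L <= 0:
        return [np.empty(0) for _ in range(n)]
    burn = 5.0
    span = burn + L
    k = int(2.0 * span + 10.0 * np.sqrt(2.0 * span) + 20)
    gaps = rng.gamma(nu, 1.0 / (2.0 * nu), size=(n, k))
    t = np.cumsum(gaps, axis=1)
    out: list[np.ndarray] = []
    for i in range(n):
        ti = t[i]
        while ti[-1] < span:  # rare top-up
            extra = np.cumsum(rng.gamma(nu, 1.0 / (2.0 * nu), size=k)) + ti[-1]
            ti = np.concatenate([ti, extra])
        chi = ti[(ti > burn) & (ti <= span)]
        keep = rng.random(chi.size) < 0.5
        out.append((chi[keep] - burn) * 100.0)
    return out


def _origins(start: int, xovers: np.ndarray, positions: np.ndarray) -> np.ndarray:
    """Haplotype index (0/1) at each marker position for one gamete."""
    counts = np.searchsorted(xovers, positions)
    return ((start + counts) % 2).astype(np.int8)


@dataclass
class GameteBatch:
    """A batch of whole-genome gametes from one parent."""

    lg_ids: list[str]
    starts: dict[str, np.ndarray]  # lg -> (n,) starting haplotype index
    crossovers: dict[str, list[np.ndarray]]  # lg -> per-gamete positions (cM)
    origins: dict[str, np.ndarray]  # lg -> (n, m_lg) haplotype index at markers

    @property
    def n(self) -> int:
        return len(self.starts[self.lg_ids[0]]) if self.lg_ids else 0

    def origin_at(self, lg_id: str, pos_cM: float) -> np.ndarray:
        st = self.starts[lg_id]
        xo = self.crossovers[lg_id]
        return np.array(
            [(s + np.searchsorted(x, pos_cM)) % 2 for s, x in zip(st, xo)], dtype=np.int8
        )

    def crossover_count(self) -> int:
        return sum(sum(len(x) for x in self.crossovers[lg]) for lg in self.lg_ids)

    def select(self, mask: np.ndarray) -> "GameteBatch":
        idx = np.flatnonzero(mask)
        return GameteBatch(
            self.lg_ids,
            {lg: self.starts[lg][idx] for lg in self.lg_ids},
            {lg: [self.crossovers[lg][i] for i in idx] for lg in self.lg_ids},
            {lg: self.origins[lg][idx] for lg in self.lg_ids},
        )

    @staticmethod
    def concat(batches: list["GameteBatch"]) -> "GameteBatch":
        b0 = batches[0]
        return GameteBatch(
            b0.lg_ids,
            {lg: np.concatenate([b.starts[lg] for b in batches]) for lg in b0.lg_ids},
            {lg: [x for b in batches for x in b.crossovers[lg]] for lg in b0.lg_ids},
            {lg: np.vstack([b.origins[lg] for b in batches]) for lg in b0.lg_ids},
        )


def simulate_gametes(
    truemap: TrueMap,
    n: int,
    model: str = "gamma",
    nu: float = 2.63,
    rng=None,
    length_factor: float = 1.0,
) -> GameteBatch:
    """Simulate ``n`` whole-genome gametes (haplotype origins per marker).

    ``length_factor`` rescales genetic distances for this parent (sex- or
    species-specific recombination rate).
    """
    rng = np.random.default_rng(rng)
    starts, xos, orig = {}, {}, {}
    for lg in truemap.lgs:
        L = lg.length * length_factor
        pos = lg.positions * length_factor
        st = rng.integers(0, 2, size=n).astype(np.int8)
        xl = simulate_crossovers(L, n, model=model, nu=nu, rng=rng)
        starts[lg.lg_id] = st
        xos[lg.lg_id] = xl
        orig[lg.lg_id] = np.vstack([_origins(s, x, pos) for s, x in zip(st, xl)])
    return GameteBatch([lg.lg_id for lg in truemap.lgs], starts, xos, orig)


def simulate_gamete(hap1, hap2, positions, length_cM=None, model="gamma", nu=2.63, rng=None):
    """One gamete on one linkage group from a phased parent.

    Returns ``(alleles, crossover_positions, origins)`` where origins are
    haplotype indices (0 = hap1) at each marker.
    """
    rng = np.random.default_rng(rng)
    hap1 = np.asarray(hap1)
    hap2 = np.asarray(hap2)
    positions = np.asarray(positions, dtype=float)
    L = float(length_cM) if length_cM is not None else (positions[-1] if positions.size else 0.0)
    start = int(rng.integers(0, 2))
    xov = simulate_crossovers(L, 1, model=model, nu=nu, rng=rng)[0]
    org = _origins(start, xov, positions)
    alleles = np.where(org == 0, hap1, hap2)
    return alleles, xov, org


def gamete_with_layout(
    truemap: TrueMap,
    counts_per_lg: dict[str, int],
    rng=None,
    margin_cM: float = 10.0,
    min_sep_cM: float = 20.0,
) -> GameteBatch:
    """One gamete whose per-LG crossover *counts* are prescribed.

    Crossover positions are drawn at least ``margin_cM`` from the LG ends and
    ``min_sep_cM`` apart, so every haplotype block is long enough to be
    identifiable at moderate marker density.  Margins shrink automatically on
    LGs too short for the requested layout.
    """
    rng = np.random.default_rng(rng)
    starts, xos, orig = {}, {}, {}
    for lg in truemap.lgs:
        k = int(counts_per_lg.get(lg.lg_id, 0))
        L = lg.length
        m, sep = margin_cM, min_sep_cM
        while k > 0 and L - 2 * m < (k - 1) * sep and m > 0.5:
            m, sep = m / 2.0, sep / 2.0
        for _ in range(10000):
            pts = np.sort(rng.uniform(m, max(L - m, m), size=k))
            if k < 2 or np.all(np.diff(pts) >= sep):
                break
        st = np.array([rng.integers(0, 2)], dtype=np.int8)
        xos[lg.lg_id] = [pts if k else np.empty(0)]
        starts[lg.lg_id] = st
        orig[lg.lg_id] = _origins(int(st[0]), xos[lg.lg_id][0], lg.positions)[None, :]
    return GameteBatch([lg.lg_id for lg in truemap.lgs], starts, xos, orig)


# ---------------------------------------------------------------------------
# selection


def apply_gametic_selection(
    batch: GameteBatch, selection: SelectionModel, sex: str, rng=None
) -> np.ndarray:
    """Boolean retention mask under rejection sampling on whole gametes."""
    rng = np.random.default_rng(rng)
    p = np.ones(batch.n)
    for locus in selection.for_sex(sex):
        carried = batch.origin_at(locus.lg_id, locus.pos_cM) == locus.favored_hap
        p *= np.where(carried, 1.0, 1.0 - locus.s)
    return rng.random(batch.n) < p


def _transmitted_alleles(truemap: TrueMap, parent: int, batch: GameteBatch) -> np.ndarray:
    """Allele transmitted by ``parent`` per marker (rows) and gamete (cols)."""
    cols = ("p1_h1", "p1_h2") if parent == 1 else ("p2_h1", "p2_h2")
    blocks = []
    for lg in truemap.lgs:
        h1 = truemap.marker_info.loc[lg.markers, cols[0]].to_numpy()
        h2 = truemap.marker_info.loc[lg.markers, cols[1]].to_numpy()
        org = batch.origins[lg.lg_id]  # (n, m)
        blocks.append(np.where(org == 0, h1[None, :], h2[None, :]).T)
    return np.vstack(blocks)


@dataclass
class SimTruth:
    """Ground truth accompanying a simulated progeny set."""

    truemap: TrueMap
    female: GameteBatch
    male: GameteBatch
    female_alleles: np.ndarray  # markers x n transmitted alleles
    male_alleles: np.ndarray
    realized_freqs: dict[tuple, float] = field(default_factory=dict)

    def transmitted_codes(self, parent: int) -> np.ndarray:
        """Truth gamete codes: index of the transmitted allele among the
        parent's sorted alleles (a = first); -1 where the parent is
        homozygous (no information)."""
        alleles = self.female_alleles if parent == 1 else self.male_alleles
        out = np.full(alleles.shape, -1, dtype=np.int8)
        for r, m in enumerate(self.truemap.markers):
            g = self.truemap.parent_genotype(parent, m)
            if g[0] == g[1]:
                continue
            out[r] = np.where(alleles[r] == g[0], 0, 1)
        return out

    def crossover_counts(self, parent: int) -> dict[str, int]:
        b = self.female if parent == 1 else self.male
        return {lg: sum(len(x) for x in b.crossovers[lg]) for lg in b.lg_ids}


def genotype_progeny(
    female_alleles: np.ndarray,
    male_alleles: np.ndarray,
    truemap: TrueMap,
    error_rate: float = 0.0,
    missing_rate: float = 0.0,
    rng=None,
    name: str = "cross",
    parent_names: tuple[str, str] = ("p1", "p2"),
    individual_prefix: str = "i",
) -> GenotypeMatrix:
    """Form observed diploid calls from transmitted alleles.

    The true genotype is the unordered pair of transmitted alleles; the
    null-allele calling rule then reports A/0 as "AA" and 0/0 as missing.
    Symmetric per-allele miscalls (to a uniformly chosen other visible
    allele) are applied at ``error_rate``, then cells are blanked at
    ``missing_rate``.
    """
    rng = np.random.default_rng(rng)
    markers = truemap.markers
    info = truemap.marker_info
    n = female_alleles.shape[1]
    calls = np.empty((len(markers), n), dtype=object)
    for r, m in enumerate(markers):
        row = info.loc[m]
        visible = sorted(
            {row[c] for c in ("p1_h1", "p1_h2", "p2_h1", "p2_h2")} - {NULL}
        )
        for j in range(n):
            a, b = female_alleles[r, j], male_alleles[r, j]
            if error_rate > 0 and len(visible) > 1:
                if rng.random() < error_rate:
                    a = _miscall(a, visible, rng)
                if rng.random() < error_rate:
                    b = _miscall(b, visible, rng)
            calls[r, j] = observed_call(a + b)
    if missing_rate > 0:
        drop = rng.random(calls.shape) < missing_rate
        calls[drop] = MISSING_CALL
    individuals = [f"{individual_prefix}{j + 1:03d}" for j in range(n)]
    df = pd.DataFrame(calls, index=markers, columns=individuals)
    parent_calls = pd.DataFrame(
        {
            "p1": [observed_call(truemap.parent_genotype(1, m)) for m in markers],
            "p2": [observed_call(truemap.parent_genotype(2, m)) for m in markers],
        },
        index=markers,
    )
    return GenotypeMatrix(df, parent_calls, info["marker_class"].copy(), name, parent_names)


def _miscall(allele: str, visible: list[str], rng) -> str:
    if allele == NULL:
        return allele  # a null allele cannot be misread; the call itself can
    others = [v for v in visible if v != allele]
    return others[int(rng.integers(0, len(others)))] if others else allele


def sample_parent_gametes(
    truemap: TrueMap,
    n: int,
    sex: str,
    selection: SelectionModel | None,
    config: SimConfig,
    rng,
    length_factor: float = 1.0,
    max_rounds: int = 200,
) -> GameteBatch:
    """Draw gametes until ``n`` survive gametic selection."""
    selection = selection or SelectionModel()
    accepted: list[GameteBatch] = []
    got = 0
    for _ in range(max_rounds):
        batch = simulate_gametes(
            truemap, max(2 * (n - got), 64), config.interference_model, config.nu, rng,
            length_factor=length_factor,
        )
        mask = apply_gametic_selection(batch, selection, sex, rng)
        if mask.any():
            accepted.append(batch.select(mask))
            got += int(mask.sum())
        if got >= n:
            full = GameteBatch.concat(accepted)
            keep = np.zeros(full.n, dtype=bool)
            keep[:n] = True
            return full.select(keep)
    raise SimulationError("selection exhausts the gamete pool")


def simulate_progeny(
    truemap: TrueMap,
    selection: SelectionModel | None,
    config: SimConfig,
    rng=None,
    *,
    female_length_factor: float = 1.0,
    male_length_factor: float = 1.0,
    zygotic_het_loci: list[tuple[str, float, float]] | None = None,
    name: str = "cross",
    parent_names: tuple[str, str] = ("p1", "p2"),
) -> tuple[GenotypeMatrix, SimTruth]:
    """Simulate a full progeny set: gametes, selection, genotyping.

    ``zygotic_het_loci`` is an optional list of ``(lg_id, pos_cM, s)``
    tuples; zygotes heterozygous by *origin* at such a locus are discarded
    with probability ``s`` (post-syngamy selection, used to contrast with
    the gametic model).
    """
    rng = np.random.default_rng(rng)
    n = config.n_progeny
    fem_parts, male_parts = [], []
    got = 0
    for _ in range(200):
        need = n - got
        fem = sample_parent_gametes(truemap, max(need, 32), "female", selection, config, rng,
                                    length_factor=female_length_factor)
        mal = sample_parent_gametes(truemap, fem.n, "male", selection, config, rng,
                                    length_factor=male_length_factor)
        keep = np.ones(fem.n, dtype=bool)
        for lg_id, pos, s in zygotic_het_loci or []:
            het = fem.origin_at(lg_id, pos) != mal.origin_at(lg_id, pos)
            # origin heterozygosity is a proxy for genotypic heterozygosity at
            # a locus where both parental haplotype pairs differ
            keep &= ~(het & (rng.random(fem.n) < s))
        fem_parts.append(fem.select(keep))
        male_parts.append(mal.select(keep))
        got += int(keep.sum())
        if got >= n:
            break
    else:
        raise SimulationError("zygotic selection exhausts the progeny pool")
    fem = GameteBatch.concat(fem_parts)
    mal = GameteBatch.concat(male_parts)
    first_n = np.zeros(fem.n, dtype=bool)
    first_n[:n] = True
    fem, mal = fem.select(first_n), mal.select(first_n)
    fa = _transmitted_alleles(truemap, 1, fem)
    ma = _transmitted_alleles(truemap, 2, mal)
    gm = genotype_progeny(
        fa, ma, truemap, config.genotyping_error_rate, config.missing_rate, rng,
        name=name, parent_names=parent_names,
    )
    truth = SimTruth(truemap, fem, mal, fa, ma)
    for locus in (selection.loci if selection else []):
        batch = fem if locus.sex == "female" else mal
        carried = batch.origin_at(locus.lg_id, locus.pos_cM) == locus.favored_hap
        truth.realized_freqs[(locus.lg_id, locus.pos_cM, locus.sex)] = float(carried.mean())
    return gm, truth


# ---------------------------------------------------------------------------
# study-like three-progeny dataset

#: reference per-LG sizes (cM) and marker counts used as the default frame
REFERENCE_LG_SIZES = [128.46, 138.92, 186.32, 89.49, 119.93, 99.80, 115.59, 118.03, 87.54]
REFERENCE_LG_MARKERS = [112, 113, 176, 104, 141, 95, 52, 61, 107]

#: default donor-gamete crossover layout: 9 crossovers
DONOR_LAYOUT = {"LG1": 1, "LG3": 2, "LG4": 2, "LG5": 2, "LG7": 1, "LG9": 1}
#: default haploid-derivative layout: 8 crossovers
HAPLOID_LAYOUT = {"LG1": 1, "LG3": 3, "LG5": 2, "LG7": 1, "LG8": 1}

#: sex-specific map-length factors (heterochiasmy) and species factors
FEMALE_LENGTH_FACTOR = 0.85
MALE_LENGTH_FACTOR = 1.07
SPECIES_LENGTH_FACTOR = {"CL": 1.0, "CH": 0.85, "PK": 0.85, "SO": 0.65, "TO": 1.0}


def _default_selection() -> dict[str, SelectionModel]:
    """Clustered gametic selection: strong, male-biased for the central parent."""
    # clusters on LG4/5/7/9 (two strong loci each: these groups are skewed
    # along most of their length in the emulated design), single strong
    # mid-LG loci on LG1/3/6, none on LG2/8; LG4 favors opposite haplotypes
    # at its two ends (selection direction flips along the group)
    cl_male = [
        SelectedLocus("LG1", 60.0, "male", 1, 0.50),
        SelectedLocus("LG3", 60.0, "male", 0, 0.50),
        SelectedLocus("LG3", 120.0, "male", 0, 0.50),
        SelectedLocus("LG4", 25.0, "male", 1, 0.60),
        SelectedLocus("LG4", 65.0, "male", 0, 0.60),
        SelectedLocus("LG5", 30.0, "male", 1, 0.60),
        SelectedLocus("LG5", 85.0, "male", 1, 0.60),
        SelectedLocus("LG6", 40.0, "male", 1, 0.45),
        SelectedLocus("LG7", 30.0, "male", 1, 0.60),
        SelectedLocus("LG7", 80.0, "male", 1, 0.60),
        SelectedLocus("LG9", 25.0, "male", 0, 0.60),
        SelectedLocus("LG9", 60.0, "male", 0, 0.60),
    ]
    cl_female = [
        SelectedLocus("LG5", 30.0, "female", 0, 0.30),
        SelectedLocus("LG9", 45.0, "female", 0, 0.25),
    ]
    ch_female = [
        SelectedLocus("LG2", 25.0, "female", 0, 0.35),
        SelectedLocus("LG8", 60.0, "female", 1, 0.35),
    ]
    pk_male = [
        SelectedLocus("LG6", 45.0, "male", 0, 0.45),
        SelectedLocus("LG9", 40.0, "male", 1, 0.40),
    ]
    so_female = [
        SelectedLocus("LG5", 80.0, "female", 1, 0.45),
        SelectedLocus("LG9", 45.0, "female", 0, 0.55),
    ]
    return {
        "CPxNC": SelectionModel(ch_female + cl_male),
        "NCxPP": SelectionModel(cl_female + pk_male),
        "SOxTO": SelectionModel(so_female),
    }


@dataclass
class StudyBundle:
    name: str
    parent1: str
    parent2: str
    genotypes: GenotypeMatrix
    truth: SimTruth


@dataclass
class StudyDataset:
    bundles: list[StudyBundle]
    truemap: TrueMap  # frame map (marker positions; parental columns unset)
    founders: pd.DataFrame  # phased haplotypes per founder, indexed by marker
    donor_crossovers: dict[str, np.ndarray]
    haploid_crossovers: dict[str, np.ndarray]
    haploid_calls: pd.Series  # single-allele calls of the haploid derivative
    central_calls: pd.Series  # observed diploid calls of the central parent
    nondonor_calls: pd.Series  # observed calls of the central parent's seed parent

    @property
    def donor_crossover_count(self) -> int:
        return int(sum(len(v) for v in self.donor_crossovers.values()))

    @property
    def haploid_crossover_count(self) -> int:
        return int(sum(len(v) for v in self.haploid_crossovers.values()))

    def bundle(self, name: str) -> StudyBundle:
        for b in self.bundles:
            if b.name == name:
                return b
        raise KeyError(name)


def _frame_map(rng, scale: float) -> tuple[list[TrueLG], pd.DataFrame]:
    lgs = []
    rows = []
    for i, (L, M) in enumerate(zip(REFERENCE_LG_SIZES, REFERENCE_LG_MARKERS), start=1):
        k = max(8, int(round(scale * M)))
        while True:
            pos = np.sort(rng.uniform(0.0, L, size=k))
            if np.all(np.diff(pos) > 1e-3):
                break
        names = [f"M{i}_{j + 1:03d}" for j in range(k)]
        lgs.append(TrueLG(f"LG{i}", names, pos))
        snp_frac, ssr_frac = 0.72, 0.26
        for name, p in zip(names, pos):
            u = rng.random()
            cls = "snp" if u < snp_frac else ("ssr" if u < snp_frac + ssr_frac else "indel")
            rows.append({"marker": name, "lg": f"LG{i}", "pos": p, "marker_class": cls})
    info = pd.DataFrame(rows).set_index("marker")
    return lgs, info


_SNP_ALLELES = ("A", "B")
_SSR_ALLELES = ("A", "B", "C", "D")


def _draw_founders(info: pd.DataFrame, lgs: list[TrueLG], rng) -> pd.DataFrame:
    """Phased founder haplotypes consistent with a prescribed donor mosaic.

    The central parent CL is the F1 of founders MD (seed parent) and SO
    (donor): its haplotypes are one MD gamete and one SO gamete.  The SO
    gamete follows the configured crossover layout, so SO's haplotype that
    the mosaic selects at each marker is pinned to CL's inherited allele.
    """
    frame = TrueMap(lgs, info.assign(p1_h1="A", p1_h2="A", p2_h1="A", p2_h2="A"))
    donor_gam = gamete_with_layout(frame, DONOR_LAYOUT, rng)
    md_gam = simulate_gametes(frame, 1, rng=rng)
    cols = {}
    for f in ("MD", "SO", "CH", "PK", "TO"):
        cols[f + "_h1"] = []
        cols[f + "_h2"] = []
    cols["CL_hmd"] = []
    cols["CL_hso"] = []
    donor_idx = {}
    md_idx = {}
    for lg in lgs:
        donor_idx.update(dict(zip(lg.markers, donor_gam.origins[lg.lg_id][0])))
        md_idx.update(dict(zip(lg.markers, md_gam.origins[lg.lg_id][0])))
    for m, row in info.iterrows():
        cls = row["marker_class"]
        if cls == "snp":
            md_allele = _SNP_ALLELES[rng.integers(0, 2)]
            other = "A" if md_allele == "B" else "B"
            cl_het = rng.random() < 0.80
            so_allele = other if cl_het else md_allele
            if rng.random() < 0.04:  # occasional null inherited by CL
                so_allele = NULL if rng.random() < 0.5 else so_allele
            # SO: pin the mosaic-selected haplotype, draw the other
            u = rng.random()
            so_vis = so_allele if so_allele != NULL else md_allele
            so_other = (("A" if so_vis == "B" else "B") if u < 0.55
                        else (NULL if u < 0.67 else so_vis))
            so = [None, None]
            so[donor_idx[m]] = so_allele
            so[1 - donor_idx[m]] = so_other
            md = [None, None]
            md[md_idx[m]] = md_allele
            md[1 - md_idx[m]] = md_allele if rng.random() < 0.80 else other
            def _hom_biased(p_hom_letter, p_hom_null, p_het, p_het_null):
                u = rng.random()
                x = _SNP_ALLELES[rng.integers(0, 2)]
                y = "A" if x == "B" else "B"
                if u < p_hom_letter:
                    return x + x
                if u < p_hom_letter + p_hom_null:
                    return NULL + NULL
                if u < p_hom_letter + p_hom_null + p_het:
                    return x + y
                return x + NULL
            ch = _hom_biased(0.78, 0.13, 0.05, 0.04)
            pk = _hom_biased(0.78, 0.13, 0.05, 0.04)
            to = _hom_biased(0.74, 0.23, 0.03, 0.00)
        else:  # ssr / indel: multi-allelic
            k = 4 if cls == "ssr" else 3
            pool = _SSR_ALLELES[:k]
            md_allele = pool[rng.integers(0, k)]
            so_allele = pool[rng.integers(0, k)]
            if rng.random() < 0.92 and so_allele == md_allele:
                so_allele = pool[(pool.index(so_allele) + 1) % k]
            so = [None, None]
            so[donor_idx[m]] = so_allele
            so[1 - donor_idx[m]] = pool[rng.integers(0, k)] if rng.random() < 0.9 else so_allele
            md = [None, None]
            md[md_idx[m]] = md_allele
            md[1 - md_idx[m]] = md_allele if rng.random() < 0.6 else pool[rng.integers(0, k)]
            def _ssr_geno():
                u = rng.random()
                a = pool[rng.integers(0, k)]
                b = pool[rng.integers(0, k)]
                if u < 0.05:
                    return NULL + NULL
                if u < 0.08:
                    return a + NULL
                return a + b
            ch, pk, to = _ssr_geno(), _ssr_geno(), _ssr_geno()
        cols["MD_h1"].append(md[0]); cols["MD_h2"].append(md[1])
        cols["SO_h1"].append(so[0]); cols["SO_h2"].append(so[1])
        cols["CH_h1"].append(ch[0]); cols["CH_h2"].append(ch[1])
        cols["PK_h1"].append(pk[0]); cols["PK_h2"].append(pk[1])
        cols["TO_h1"].append(to[0]); cols["TO_h2"].append(to[1])
        cols["CL_hmd"].append(md[md_idx[m]])
        cols["CL_hso"].append(so[donor_idx[m]])
    founders = pd.DataFrame(cols, index=info.index)
    founders.attrs["donor_crossovers"] = {
        lg.lg_id: donor_gam.crossovers[lg.lg_id][0] for lg in lgs
    }
    return founders


def _cross_truemap(lgs, info, founders, p1: str, p2: str) -> TrueMap:
    def haps(f):
        if f == "CL":
            return founders["CL_hmd"], founders["CL_hso"]
        return founders[f + "_h1"], founders[f + "_h2"]

    a1, a2 = haps(p1)
    b1, b2 = haps(p2)
    mi = info.assign(p1_h1=a1, p1_h2=a2, p2_h1=b1, p2_h2=b2)
    return TrueMap(lgs, mi)


def make_study_like_dataset(
    seed: int,
    scale: float = 1.0,
    error_rate: float = 0.002,
    missing_rate: float = 0.03,
    n_progeny: tuple[int, int, int] = (156, 140, 147),
    haploid_layout: dict[str, int] | None = None,
) -> StudyDataset:
    """Three F1 progeny sets with the structure of the citrus design.

    Crosses: CH x CL (n=156, central parent CL as male), CL x PK (n=140, CL
    as female) and SO x TO (n=147).  CL itself is an F1 of MD x SO whose
    SO-derived haplotype carries a 9-crossover layout; a haploid derivative
    of CL carries an 8-crossover layout.  Identical seeds give identical
    datasets.
    """
    ss = np.random.SeedSequence(int(seed))
    r_frame, r_found, r_hap, r1, r2, r3 = [np.random.default_rng(s) for s in ss.spawn(6)]
    lgs, info = _frame_map(r_frame, scale)
    founders = _draw_founders(info, lgs, r_found)
    sel = _default_selection()

    frame = TrueMap(lgs, info.assign(p1_h1="A", p1_h2="A", p2_h1="A", p2_h2="A"))
    hap_gam = gamete_with_layout(frame, haploid_layout or HAPLOID_LAYOUT, r_hap)
    hap_idx = {}
    for lg in lgs:
        hap_idx.update(dict(zip(lg.markers, hap_gam.origins[lg.lg_id][0])))
    hap_alleles = pd.Series(
        {
            m: (founders.loc[m, "CL_hmd"] if hap_idx[m] == 0 else founders.loc[m, "CL_hso"])
            for m in info.index
        }
    ).reindex(info.index)
    haploid_calls = hap_alleles.where(hap_alleles != NULL, MISSING_CALL)

    specs = [
        ("CPxNC", "CH", "CL", n_progeny[0], r1),
        ("NCxPP", "CL", "PK", n_progeny[1], r2),
        ("SOxTO", "SO", "TO", n_progeny[2], r3),
    ]
    bundles = []
    for name, p1, p2, n, rng in specs:
        tm = _cross_truemap(lgs, info, founders, p1, p2)
        cfg = SimConfig(n_progeny=n, genotyping_error_rate=error_rate,
                        missing_rate=missing_rate)
        gm, truth = simulate_progeny(
            tm, sel[name], cfg, rng,
            female_length_factor=FEMALE_LENGTH_FACTOR * SPECIES_LENGTH_FACTOR[p1],
            male_length_factor=MALE_LENGTH_FACTOR * SPECIES_LENGTH_FACTOR[p2],
            name=name, parent_names=(p1, p2),
        )
        bundles.append(StudyBundle(name, p1, p2, gm, truth))

    central_calls = pd.Series(
        {m: observed_call(founders.loc[m, "CL_hmd"] + founders.loc[m, "CL_hso"])
         for m in info.index}
    ).reindex(info.index)
    nondonor_calls = pd.Series(
        {m: observed_call(founders.loc[m, "MD_h1"] + founders.loc[m, "MD_h2"])
         for m in info.index}
    ).reindex(info.index)

    return StudyDataset(
        bundles=bundles,
        truemap=frame,
        founders=founders,
        donor_crossovers=founders.attrs["donor_crossovers"],
        haploid_crossovers={lg.lg_id: hap_gam.crossovers[lg.lg_id][0] for lg in lgs},
        haploid_calls=haploid_calls,
        central_calls=central_calls,
        nondonor_calls=nondonor_calls,
    )
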