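"""Segregation codification for outbred F1 (CP population) genotype data.

Raw progeny calls are diploid genotypes over abstract allele symbols
(A, B, C, D), where a null (non-amplifying) allele "0" makes a heterozygote
look homozygous: a true A/0 individual is called "AA" and a 0/0 individual
is missing.  The routines here recover the *true* parental configuration at
each locus by enumerating every configuration compatible with the observed
parental calls, keeping those whose reachable progeny-call classes match the
classes actually observed, and then assign a JoinMap-style segregation type:

====== =========================================================
nnxnp  second parent heterozygous, first homozygous (testcross)
lmxll  first parent heterozygous, second homozygous
hkxhk  both parents heterozygous for the same two alleles
efxeg  both heterozygous, three distinct alleles
abxcd  both heterozygous, four distinct alleles
====== =========================================================

``hkxhk`` markers are excluded from mapping (parental origin of the
heterozygous progeny class is unresolvable, so only half the population is
informative).  Configurations where a clean heterozygote meets a null-carrying
heterozygote (AB x A0) are analysed for the clean parent only, i.e. recoded
lmxll (or nnxnp for the reciprocal), pooling the indistinguishable AA/A0
progeny into the homozygous class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations_with_replacement

import numpy as np
import pandas as pd
from scipy.stats import binom

from ._util import CODE_MISSING

MISSING_CALL = "--"
NULL = "0"

SEG_TYPES = ("nnxnp", "lmxll", "hkxhk", "efxeg", "abxcd")

__all__ = [
    "LocusConfig",
    "GameteMatrix",
    "GenotypeMatrix",
    "Census",
    "DataIntegrityError",
    "canonical_genotype",
    "observed_call",
    "infer_parental_configuration",
    "assign_segregation_type",
    "derive_gamete_matrix",
    "census_segregation_types",
    "code_markers",
]


class DataIntegrityError(ValueError):
    """A progeny class is impossible under every parental configuration."""

    def __init__(self, message: str, individuals: list[str] | None = None):
        super().__init__(message)
        self.individuals = individuals or []


def canonical_genotype(alleles) -> str:
    """Two-symbol genotype string, letters first, null ('0') last."""
    a, b = sorted(alleles, key=lambda c: (c == NULL, c))
    return a + b


def observed_call(true_genotype: str) -> str:
    """Apply the null-allele calling rule to a true genotype.

    A/0 is reported as the homozygous call AA, 0/0 does not amplify and is
    reported missing.
    """
    g = canonical_genotype(true_genotype)
    if g == NULL + NULL:
        return MISSING_CALL
    if g[1] == NULL:
        return g[0] + g[0]
    return g


def _is_het(g: str) -> bool:
    return g[0] != g[1]


def _null_class(g: str) -> str:
    if g == NULL + NULL:
        return "hom_null"
    if NULL in g:
        return "het_null"
    return "none"


@dataclass
class LocusConfig:
    """Resolved parental configuration and segregation type at one locus."""

    marker: str
    p1: str  # true genotype of the first-listed parent, e.g. "AB", "A0"
    p2: str
    seg_type: str  # one of SEG_TYPES or "uninformative"
    excluded: bool = False
    reason: str = ""
    n_informative: int = 0
    marker_class: str = ""  # snp | ssr | indel (optional)

    @property
    def null_classes(self) -> tuple[str, str]:
        return _null_class(self.p1), _null_class(self.p2)

    def mapped_for(self, parent: int) -> bool:
        """Whether this locus contributes gamete codes for parent 1 or 2."""
        if self.excluded:
            return False
        if parent == 1:
            return self.seg_type in ("lmxll", "efxeg", "abxcd")
        return self.seg_type in ("nnxnp", "efxeg", "abxcd")

    def parent_alleles(self, parent: int) -> tuple[str, str]:
        g = self.p1 if parent == 1 else self.p2
        gg = canonical_genotype(g)
        return gg[0], gg[1]


@dataclass
class GameteMatrix:
    """Per-parent haplotype-contribution codes (a/b) per marker and progeny."""

    parent: str
    markers: list[str]
    individuals: list[str]
    codes: np.ndarray  # int8: 0 = a, 1 = b, -1 = missing
    allele_of_code: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.int8)
        assert self.codes.shape == (len(self.markers), len(self.individuals))

    @property
    def n_progeny(self) -> int:
        return len(self.individuals)

    def row(self, marker: str) -> np.ndarray:
        return self.codes[self.markers.index(marker)]

    def subset(self, markers: list[str]) -> "GameteMatrix":
        rows = [self.markers.index(m) for m in markers]
        return GameteMatrix(
            self.parent,
            list(markers),
            list(self.individuals),
            self.codes[rows].copy(),
            {m: self.allele_of_code[m] for m in markers if m in self.allele_of_code},
        )

    def to_frame(self) -> pd.DataFrame:
        from ._util import codes_to_strings

        return pd.DataFrame(codes_to_strings(self.codes), index=self.markers, columns=self.individuals)


@dataclass
class GenotypeMatrix:
    """Observed diploid calls, markers x individuals, with parental calls."""

    calls: pd.DataFrame  # strings like "AB", MISSING_CALL when absent
    parent_calls: pd.DataFrame  # index = markers, columns = ["p1", "p2"]
    marker_class: pd.Series  # marker -> snp | ssr | indel
    name: str = "cross"
    parent_names: tuple[str, str] = ("p1", "p2")

    @property
    def markers(self) -> list[str]:
        return list(self.calls.index)

    @property
    def individuals(self) -> list[str]:
        return list(self.calls.columns)


# ---------------------------------------------------------------------------
# configuration inference


def _candidate_genotypes(call: str | None, universe: tuple[str, ...]) -> list[str]:
    """True genotypes compatible with an observed parental call."""
    if call is None or call == MISSING_CALL:
        return [canonical_genotype(p) for p in combinations_with_replacement(universe + (NULL,), 2)]
    if call[0] != call[1]:
        return [canonical_genotype(call)]
    # homozygous-looking: may hide a null
    return [call, canonical_genotype(call[0] + NULL)]


def _class_probabilities(g1: str, g2: str) -> dict[str, float]:
    """Mendelian probabilities of each non-missing progeny *call* class."""
    probs: dict[str, float] = {}
    for a1 in g1:
        for a2 in g2:
            c = observed_call(a1 + a2)
            if c != MISSING_CALL:
                probs[c] = probs.get(c, 0.0) + 0.25
    return probs


def _transmission_map(g1: str, g2: str) -> dict[str, tuple[set[str], set[str]]]:
    """call class -> (possible p1 transmitted alleles, possible p2 alleles)."""
    out: dict[str, tuple[set[str], set[str]]] = {}
    for a1 in g1:
        for a2 in g2:
            c = observed_call(a1 + a2)
            if c == MISSING_CALL:
                continue
            s1, s2 = out.setdefault(c, (set(), set()))
            s1.add(a1)
            s2.add(a2)
    return out


def assign_segregation_type(g1: str, g2: str) -> tuple[str, bool, str]:
    """Segregation type plus (excluded, reason) for resolved true genotypes."""
    h1, h2 = _is_het(g1), _is_het(g2)
    if not h1 and not h2:
        return "uninformative", True, "no_segregation"
    if h1 and h2:
        n1, n2 = NULL in g1, NULL in g2
        if n1 and n2:
            # A0 x A0 / A0 x B0: the null-vs-null cells are uninformative
            return "uninformative", True, "null_by_null"
        if n1 or n2:
            # AB x A0 analysed for the clean heterozygous parent only
            t = "nnxnp" if n1 else "lmxll"
            return t, False, ""
        alleles = set(g1) | set(g2)
        if len(alleles) == 2:
            return "hkxhk", True, "hk_excluded"
        if len(alleles) == 3:
            return "efxeg", False, ""
        return "abxcd", False, ""
    return ("lmxll", False, "") if h1 else ("nnxnp", False, "")


def _signature(g1: str, g2: str):
    seg, excl, _ = assign_segregation_type(g1, g2)
    tm = _transmission_map(g1, g2)
    sig = []
    resolved1: set[str] = set()
    resolved2: set[str] = set()
    for c in sorted(tm):
        s1, s2 = tm[c]
        a1 = next(iter(s1)) if len(s1) == 1 and seg_maps(seg, excl, 1) else None
        a2 = next(iter(s2)) if len(s2) == 1 and seg_maps(seg, excl, 2) else None
        if a1 is not None:
            resolved1.add(a1)
        if a2 is not None:
            resolved2.add(a2)
        sig.append((c, a1, a2))
    # a configuration that resolves no segregating gamete codes is, for all
    # mapping purposes, uninformative — collapse so it cannot create
    # spurious ambiguity with plain homozygous configurations
    if seg == "uninformative" or (not excl and len(resolved1) < 2 and len(resolved2) < 2):
        return ("uninformative", True, ())
    return (seg, excl, tuple(sig))


def seg_maps(seg: str, excluded: bool, parent: int) -> bool:
    if excluded:
        return False
    if parent == 1:
        return seg in ("lmxll", "efxeg", "abxcd")
    return seg in ("nnxnp", "efxeg", "abxcd")


def infer_parental_configuration(
    marker: str,
    p1_call: str | None,
    p2_call: str | None,
    progeny_counts: dict[str, int],
    *,
    min_informative: int = 20,
    assumed_error: float = 0.01,
    presence_alpha: float = 1e-3,
    min_class_prob: float = 0.05,
    marker_class: str = "",
) -> LocusConfig:
    """Resolve the true parental genotypes (including nulls) at one locus.

    A progeny call class counts as *present* when its count is too large to
    be explained by miscalls alone (binomial test at ``presence_alpha``
    against ``assumed_error``).  A candidate configuration survives when all
    present classes are reachable and every class it predicts with Mendelian
    probability >= ``min_class_prob`` is present.  Surviving candidates that
    differ in segregation type or in how progeny classes resolve to parental
    gametes leave the marker flagged ambiguous; a marker is never guessed.

    Raises :class:`DataIntegrityError` when an observed class is impossible
    under every configuration (e.g. a "CC" progeny of an AB x AB SNP).
    """
    counts = {c: int(v) for c, v in progeny_counts.items() if c != MISSING_CALL and v > 0}
    n = sum(counts.values())
    if n < min_informative:
        return LocusConfig(marker, p1_call or MISSING_CALL, p2_call or MISSING_CALL,
                           "uninformative", True, "too_few_progeny", n, marker_class)

    universe = tuple(sorted({a for c in counts for a in c if a != NULL}
                            | {a for c in (p1_call, p2_call) if c and c != MISSING_CALL
                               for a in c if a != NULL}))
    present = {
        c for c, v in counts.items()
        if binom.sf(v - 1, n, assumed_error) < presence_alpha
    }
    if not present:
        return LocusConfig(marker, p1_call or MISSING_CALL, p2_call or MISSING_CALL,
                           "uninformative", True, "no_reliable_classes", n, marker_class)

    cands = []
    for g1 in _candidate_genotypes(p1_call, universe):
        for g2 in _candidate_genotypes(p2_call, universe):
            probs = _class_probabilities(g1, g2)
            if not present <= set(probs):
                continue
            if any(p >= min_class_prob and c not in present for c, p in probs.items()):
                continue
            cands.append((g1, g2))

    if not cands:
        offending = sorted(present)
        raise DataIntegrityError(
            f"{marker}: progeny classes {offending} are impossible under every "
            f"configuration compatible with parental calls ({p1_call}, {p2_call})",
        )

    sigs = {_signature(g1, g2) for g1, g2 in cands}
    if len(sigs) > 1:
        return LocusConfig(marker, p1_call or MISSING_CALL, p2_call or MISSING_CALL,
                           "uninformative", True, "ambiguous", n, marker_class)

    # canonical representative: fewest null alleles, then lexicographic
    g1, g2 = min(cands, key=lambda gg: (gg[0].count(NULL) + gg[1].count(NULL), gg))
    if next(iter(sigs)) == ("uninformative", True, ()):
        return LocusConfig(marker, g1, g2, "uninformative", True, "no_segregation",
                           n, marker_class)
    seg, excl, reason = assign_segregation_type(g1, g2)
    return LocusConfig(marker, g1, g2, seg, excl, reason, n, marker_class)


def code_markers(gm: GenotypeMatrix, **kwargs) -> dict[str, LocusConfig]:
    """Infer a :class:`LocusConfig` for every marker of a genotype matrix.

    Loci raising a data-integrity error are excluded with reason
    "incompatible" instead of aborting the run.
    """
    out: dict[str, LocusConfig] = {}
    classes = gm.marker_class
    for m in gm.markers:
        counts = gm.calls.loc[m].value_counts().to_dict()
        p1c, p2c = gm.parent_calls.loc[m, "p1"], gm.parent_calls.loc[m, "p2"]
        try:
            cfg = infer_parental_configuration(
                m, p1c, p2c, counts, marker_class=str(classes.get(m, "")), **kwargs
            )
        except DataIntegrityError:
            cfg = LocusConfig(m, p1c, p2c, "uninformative", True, "incompatible",
                              int(sum(v for c, v in counts.items() if c != MISSING_CALL)),
                              str(classes.get(m, "")))
        out[m] = cfg
    return out


# ---------------------------------------------------------------------------
# gamete extraction


def derive_gamete_matrix(
    gm: GenotypeMatrix, configs: dict[str, LocusConfig], parent: int, label: str | None = None
) -> GameteMatrix:
    """Extract the chosen parent's transmitted-allele codes (a/b) per progeny.

    For every marker mapped for that parent, a progeny call resolves to code
    "a" or "b" when *all* gamete combinations consistent with the call agree
    on the allele the parent transmitted; otherwise the cell is missing
    (e.g. the pooled AA/A0 class of a recoded AB x A0 marker resolves for the
    AB parent but not for the null parent).
    """
    markers = [m for m in gm.markers if m in configs and configs[m].mapped_for(parent)]
    individuals = gm.individuals
    codes = np.full((len(markers), len(individuals)), CODE_MISSING, dtype=np.int8)
    allele_of_code: dict[str, tuple[str, str]] = {}
    calls = gm.calls
    for r, m in enumerate(markers):
        cfg = configs[m]
        a0, a1 = cfg.parent_alleles(parent)
        allele_of_code[m] = (a0, a1)
        tm = _transmission_map(cfg.p1, cfg.p2)
        lut = {}
        for c, (s1, s2) in tm.items():
            s = s1 if parent == 1 else s2
            if len(s) == 1:
                al = next(iter(s))
                lut[c] = 0 if al == a0 else 1
        row = calls.loc[m]
        for j, v in enumerate(row.to_numpy()):
            if v in lut:
                codes[r, j] = lut[v]
    who = label or (gm.parent_names[0] if parent == 1 else gm.parent_names[1])
    return GameteMatrix(who, markers, list(individuals), codes, allele_of_code)


@dataclass
class Census:
    """Tally of segregation types and parental null-allele classes."""

    seg_counts: pd.Series  # index: seg type (+ "uninformative"), values: counts
    null_counts: pd.DataFrame  # index: parent, columns: hom_null / het_null
    n_mapped: int


def census_segregation_types(configs: dict[str, LocusConfig]) -> Census:
    """Tabulate segregation types and null-allele configurations."""
    types = [c.seg_type for c in configs.values()]
    seg = pd.Series(types).value_counts().reindex(
        list(SEG_TYPES) + ["uninformative"], fill_value=0
    ) if types else pd.Series(0, index=list(SEG_TYPES) + ["uninformative"])
    nulls = pd.DataFrame(0, index=["p1", "p2"], columns=["hom_null", "het_null"])
    for c in configs.values():
        for p, nc in zip(("p1", "p2"), c.null_classes):
            if nc != "none":
                nulls.loc[p, nc] += 1
    n_mapped = sum(1 for c in configs.values() if c.mapped_for(1) or c.mapped_for(2))
    return Census(seg.astype(int), nulls, n_mapped)
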