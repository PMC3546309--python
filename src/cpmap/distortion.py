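"""Segregation-distortion scanning and the gametic-vs-zygotic selection check.

Each informative marker of a parent segregates 1:1 in that parent's gametes
under Mendelian expectation; departures are scored with a one-df chi-square
conformity test.  Allele-origin excess profiles translate the same counts
into the frequency of a designated ancestral allele minus 0.5, with a
normal-approximation significance envelope — the natural display when the
parent is itself an interspecific F1 and its two haplotypes have known
ancestry.

Wright's fixation index separates gametic from zygotic selection: selection
acting on gametes (before syngamy) shifts allele frequencies but leaves the
progeny genotype frequencies at the random-union-of-gametes expectation
(F ~ 0), whereas selection on zygote genotypes (e.g. against heterozygotes)
produces a heterozygote deficit (F > 0).  Because a testcross locus exposes
only one parent's gamete, the two mechanisms are confounded there; F is
therefore evaluated at loci heterozygous in both parents.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom, chi2 as chi2_dist, norm

from ._util import CODE_MISSING
from .segcoding import NULL, GenotypeMatrix, LocusConfig, _transmission_map
from .ordering import GeneticMap
from .segcoding import GameteMatrix

__all__ = [
    "DistortionRecord",
    "chi2_segregation_test",
    "scan_gametes",
    "skewed_fraction",
    "allele_origin_excess",
    "fixation_index",
]


@dataclass
class DistortionRecord:
    marker: str
    a_count: int
    b_count: int
    chi2: float
    p: float
    skewed: bool
    origin_excess: float | None = None


def chi2_segregation_test(a_count: int, b_count: int, alpha: float = 0.05,
                          marker: str = "") -> DistortionRecord:
    """One-df chi-square conformity test of gamete counts against 1:1."""
    n = a_count + b_count
    if n == 0:
        raise ValueError("no informative gametes: test undefined")
    half = n / 2.0
    stat = (a_count - half) ** 2 / half + (b_count - half) ** 2 / half
    p = float(chi2_dist.sf(stat, df=1))
    return DistortionRecord(marker, int(a_count), int(b_count), float(stat), p, p < alpha)


def scan_gametes(gam: GameteMatrix, alpha: float = 0.05) -> pd.DataFrame:
    """Per-marker 1:1 conformity tests over a gamete matrix."""
    rows = []
    for i, m in enumerate(gam.markers):
        col = gam.codes[i]
        a = int(np.count_nonzero(col == 0))
        b = int(np.count_nonzero(col == 1))
        if a + b == 0:
            continue
        rec = chi2_segregation_test(a, b, alpha, m)
        rows.append({"marker": m, "a": a, "b": b, "chi2": rec.chi2, "p": rec.p,
                     "skewed": rec.skewed})
    return pd.DataFrame(rows).set_index("marker") if rows else pd.DataFrame(
        columns=["a", "b", "chi2", "p", "skewed"])


def skewed_fraction(gmap: GeneticMap, records: pd.DataFrame,
                    alpha: float = 0.05) -> tuple[pd.Series, float]:
    """Proportion of mapped markers with segregation p < alpha, per LG and total."""
    per_lg = {}
    tot_n = tot_d = 0
    for lg in gmap.linkage_groups:
        ms = [m for m in lg.markers if m in records.index]
        d = sum(1 for m in ms if records.loc[m, "p"] < alpha)
        per_lg[lg.lg_id] = d / len(ms) if ms else 0.0
        tot_n += len(ms)
        tot_d += d
    return pd.Series(per_lg), (tot_d / tot_n if tot_n else 0.0)


def allele_origin_excess(
    gam: GameteMatrix,
    origin_table: dict[str, int],
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, list[str]]:
    """Frequency of the designated ancestral allele minus 0.5, per marker.

    ``origin_table`` maps marker -> gamete code (0/1) carrying the ancestral
    allele.  The significance envelope is the two-sided normal band
    z_{alpha/2} / (2 sqrt(n)) around 0.  Markers without an assigned origin
    are omitted and returned separately.
    """
    z = norm.ppf(1.0 - alpha / 2.0)
    rows, omitted = [], []
    for i, m in enumerate(gam.markers):
        if m not in origin_table:
            omitted.append(m)
            continue
        col = gam.codes[i]
        scored = col != CODE_MISSING
        n = int(scored.sum())
        if n == 0:
            omitted.append(m)
            continue
        anc = int(np.count_nonzero(col[scored] == origin_table[m]))
        excess = anc / n - 0.5
        env = z / (2.0 * np.sqrt(n))
        rows.append({"marker": m, "excess": excess, "envelope": env, "n": n,
                     "significant": abs(excess) > env})
    df = pd.DataFrame(rows).set_index("marker") if rows else pd.DataFrame(
        columns=["excess", "envelope", "n", "significant"])
    return df, omitted


def excess_peak(excess: pd.Series, positions: pd.Series,
                half_window_cM: float = 7.5) -> float:
    """Position of the largest |origin excess|, from a smoothed profile.

    Per-marker excess values carry binomial noise of order 1/(2 sqrt(n)),
    comparable to the decay of a real selection signal over ~10 cM, so the
    raw argmax is an unstable peak estimator.  The profile is averaged over
    a sliding cM window (selection signals decay smoothly with recombination
    distance) and the peak is the position maximising |window mean| scaled by
    the square root of the window size: near the chromosome ends the window
    holds fewer markers and a raw mean there is noisier, which would
    otherwise produce spurious terminal peaks.
    """
    pos = positions.loc[excess.index].to_numpy(float)
    val = excess.to_numpy(float)
    order = np.argsort(pos)
    pos, val = pos[order], val[order]
    z = np.empty(pos.size)
    for i, p in enumerate(pos):
        w = val[np.abs(pos - p) <= half_window_cM]
        z[i] = np.abs(w.mean()) * np.sqrt(w.size)
    return float(pos[int(np.argmax(z))])


# ---------------------------------------------------------------------------
# Wright's fixation index


def _phi_and_perm(x: np.ndarray, y: np.ndarray, n_perm: int, rng) -> tuple[float, float]:
    """Correlation between uniting gametes and a label-permutation p-value."""

    def phi(a, b):
        n11 = np.count_nonzero(a & b)
        n10 = np.count_nonzero(a & ~b)
        n01 = np.count_nonzero(~a & b)
        n00 = np.count_nonzero(~a & ~b)
        denom = (n11 + n10) * (n01 + n00) * (n11 + n01) * (n10 + n00)
        return (n11 * n00 - n10 * n01) / np.sqrt(denom) if denom > 0 else 0.0

    obs = phi(x, y)
    hits = 0
    yy = y.copy()
    for _ in range(n_perm):
        rng.shuffle(yy)
        if abs(phi(x, yy)) >= abs(obs) - 1e-12:
            hits += 1
    return float(obs), (hits + 1) / (n_perm + 1)


def fixation_index(
    genotypes: GenotypeMatrix,
    configs: dict[str, LocusConfig],
    n_perm: int = 200,
    alpha: float = 0.05,
    rng=None,
) -> pd.DataFrame:
    """Per-marker Wright F with a test of random union of gametes.

    Fully informative loci (ef x eg, ab x cd without nulls) resolve both
    parental gametes per progeny; F is the correlation between the uniting
    gametes and the test permutes one parent's gametes across progeny.
    Biallelic hk x hk loci use F = 1 - H_obs/H_exp with H_exp = 2 p q from
    progeny allele frequencies and a binomial test of the heterozygote
    count.  Monomorphic or testcross loci are skipped.
    """
    rng = np.random.default_rng(rng)
    rows = []
    for m, cfg in configs.items():
        if cfg.excluded and cfg.reason != "hk_excluded":
            continue
        g1, g2 = cfg.p1, cfg.p2
        if NULL in g1 or NULL in g2:
            continue
        het1, het2 = g1[0] != g1[1], g2[0] != g2[1]
        if not (het1 and het2):
            continue
        calls = genotypes.calls.loc[m]
        if cfg.seg_type in ("efxeg", "abxcd"):
            tm = _transmission_map(g1, g2)
            xs, ys = [], []
            for v in calls:
                if v in tm:
                    s1, s2 = tm[v]
                    if len(s1) == 1 and len(s2) == 1:
                        xs.append(next(iter(s1)) == g1[0])
                        ys.append(next(iter(s2)) == g2[0])
            if len(xs) < 10:
                continue
            x = np.asarray(xs)
            y = np.asarray(ys)
            if x.all() or (~x).all() or y.all() or (~y).all():
                continue
            f, p = _phi_and_perm(x, y, n_perm, rng)
            rows.append({"marker": m, "F": f, "p": p, "method": "gamete_permutation",
                         "n": len(xs)})
        elif cfg.seg_type == "hkxhk":
            a, b = sorted(set(g1))
            vals = [v for v in calls if v != "--"]
            n = len(vals)
            if n < 10:
                continue
            n_het = sum(1 for v in vals if v[0] != v[1])
            p_a = sum(v.count(a) for v in vals) / (2.0 * n)
            h_exp = 2.0 * p_a * (1.0 - p_a)
            if h_exp <= 0:
                continue
            f = 1.0 - (n_het / n) / h_exp
            lo = float(binom.cdf(n_het, n, h_exp))
            hi = float(binom.sf(n_het - 1, n, h_exp))
            p = min(1.0, 2.0 * min(lo, hi))
            rows.append({"marker": m, "F": f, "p": p, "method": "het_binomial", "n": n})
    cols = ["F", "p", "method", "n"]
    out = pd.DataFrame(rows).set_index("marker") if rows else pd.DataFrame(columns=cols)
    out.attrs["alpha"] = alpha
    return out
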