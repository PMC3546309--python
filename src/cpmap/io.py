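"""Plain-text readers and writers: genotype TSV, JoinMap-style ``.loc``
files, map tables, and run manifests.

All formats are line-oriented text; malformed input raises
:class:`ParseError` naming the offending line.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import codes_to_strings, strings_to_codes
from .ordering import GeneticMap
from .segcoding import (
    MISSING_CALL,
    SEG_TYPES,
    GameteMatrix,
    GenotypeMatrix,
    LocusConfig,
    _transmission_map,
)

__all__ = [
    "ParseError",
    "write_genotype_tsv",
    "read_genotype_tsv",
    "write_gamete_tsv",
    "read_gamete_tsv",
    "write_joinmap_loc",
    "read_joinmap_loc",
    "write_map_tsv",
    "read_map_tsv",
    "write_manifest",
]


class ParseError(ValueError):
    """Malformed input file; the message names the file and line number."""


# ---------------------------------------------------------------------------
# genotype matrices


def write_genotype_tsv(gm: GenotypeMatrix, path) -> None:
    """rows = markers; first columns: marker id, class, parental calls."""
    df = pd.DataFrame(index=gm.calls.index)
    df["class"] = gm.marker_class.reindex(gm.calls.index)
    df["parent1"] = gm.parent_calls["p1"]
    df["parent2"] = gm.parent_calls["p2"]
    out = pd.concat([df, gm.calls], axis=1)
    out.index.name = "marker"
    out.to_csv(path, sep="\t")


def read_genotype_tsv(path, name: str = "cross",
                      parent_names: tuple[str, str] = ("p1", "p2")) -> GenotypeMatrix:
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = lines[0].split("\t")
    required = ["marker", "class", "parent1", "parent2"]
    if header[:4] != required:
        raise ParseError(f"{path}:1: header must start with {required}")
    individuals = header[4:]
    rows, classes, p1, p2, markers = [], [], [], [], []
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != len(header):
            raise ParseError(f"{path}:{ln}: expected {len(header)} fields, got {len(parts)}")
        markers.append(parts[0])
        classes.append(parts[1])
        p1.append(parts[2])
        p2.append(parts[3])
        rows.append(parts[4:])
    calls = pd.DataFrame(rows, index=markers, columns=individuals)
    parent_calls = pd.DataFrame({"p1": p1, "p2": p2}, index=markers)
    return GenotypeMatrix(calls, parent_calls, pd.Series(classes, index=markers),
                          name, parent_names)


# ---------------------------------------------------------------------------
# gamete matrices


def write_gamete_tsv(gam: GameteMatrix, path) -> None:
    df = pd.DataFrame(codes_to_strings(gam.codes), index=gam.markers,
                      columns=gam.individuals)
    df.insert(0, "allele_b", [gam.allele_of_code.get(m, ("a", "b"))[1] for m in gam.markers])
    df.insert(0, "allele_a", [gam.allele_of_code.get(m, ("a", "b"))[0] for m in gam.markers])
    df.index.name = "marker"
    with open(path, "w") as fh:
        fh.write(f"# parent\t{gam.parent}\n")
        df.to_csv(fh, sep="\t")


def read_gamete_tsv(path) -> GameteMatrix:
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or not lines[0].startswith("# parent\t"):
        raise ParseError(f"{path}:1: expected '# parent<TAB><name>' header")
    parent = lines[0].split("\t", 1)[1]
    header = lines[1].split("\t")
    if header[:3] != ["marker", "allele_a", "allele_b"]:
        raise ParseError(f"{path}:2: bad column header")
    individuals = header[3:]
    markers, alleles, rows = [], {}, []
    for ln, line in enumerate(lines[2:], start=3):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != len(header):
            raise ParseError(f"{path}:{ln}: expected {len(header)} fields")
        bad = [c for c in parts[3:] if c not in ("a", "b", "-")]
        if bad:
            raise ParseError(f"{path}:{ln}: illegal gamete codes {sorted(set(bad))}")
        markers.append(parts[0])
        alleles[parts[0]] = (parts[1], parts[2])
        rows.append(parts[3:])
    codes = strings_to_codes(np.asarray(rows)) if rows else np.empty((0, len(individuals)), np.int8)
    return GameteMatrix(parent, markers, individuals, codes, alleles)


# ---------------------------------------------------------------------------
# JoinMap-style .loc (CP population)


def _loc_symbols(cfg: LocusConfig) -> tuple[dict, dict]:
    """Per-parent maps: allele -> JoinMap letter for this locus."""
    a1 = cfg.parent_alleles(1)
    a2 = cfg.parent_alleles(2)
    t = cfg.seg_type
    if t == "lmxll":
        return {a1[0]: "l", a1[1]: "m"}, {}
    if t == "nnxnp":
        return {}, {a2[0]: "n", a2[1]: "p"}
    if t == "efxeg":
        shared = (set(a1) & set(a2)) or {a1[0]}
        e = sorted(shared)[0]
        f = a1[0] if a1[1] == e else a1[1]
        g = a2[0] if a2[1] == e else a2[1]
        return {e: "e", f: "f"}, {e: "e", g: "g"}
    if t == "abxcd":
        return {a1[0]: "a", a1[1]: "b"}, {a2[0]: "c", a2[1]: "d"}
    if t == "hkxhk":
        return {a1[0]: "h", a1[1]: "k"}, {a2[0]: "h", a2[1]: "k"}
    return {}, {}


def write_joinmap_loc(gm: GenotypeMatrix, configs: dict[str, LocusConfig], path,
                      name: str = "population") -> None:
    """CP-coded locus file for the informative (non-excluded) markers."""
    included = [m for m in gm.markers
                if m in configs and not configs[m].excluded
                and configs[m].seg_type in SEG_TYPES]
    lines = [f"name = {name}", "popt = CP", f"nloc = {len(included)}",
             f"nind = {len(gm.individuals)}", ""]
    for m in included:
        cfg = configs[m]
        s1, s2 = _loc_symbols(cfg)
        tm = _transmission_map(cfg.p1, cfg.p2)
        codes = []
        for v in gm.calls.loc[m]:
            sym = "--"
            if v in tm:
                g1s, g2s = tm[v]
                c1 = s1.get(next(iter(g1s))) if len(g1s) == 1 else None
                c2 = s2.get(next(iter(g2s))) if len(g2s) == 1 else None
                if cfg.seg_type == "lmxll":
                    sym = "l" + c1 if c1 else "--"
                elif cfg.seg_type == "nnxnp":
                    sym = "n" + c2 if c2 else "--"
                elif cfg.seg_type in ("efxeg", "abxcd") and c1 and c2:
                    sym = c1 + c2
            codes.append(sym)
        lines.append(f"{m} <{cfg.seg_type}> {{--}}\t" + " ".join(codes))
    Path(path).write_text("\n".join(lines) + "\n")


def read_joinmap_loc(path) -> tuple[dict, pd.DataFrame, dict[str, str]]:
    """Parse a CP ``.loc`` file: header dict, code matrix, seg-type tags."""
    path = Path(path)
    lines = path.read_text().splitlines()
    header: dict[str, str] = {}
    body_start = 0
    for ln, line in enumerate(lines, start=1):
        if not line.strip():
            body_start = ln
            break
        if "=" not in line:
            raise ParseError(f"{path}:{ln}: expected 'key = value' header line")
        k, v = (x.strip() for x in line.split("=", 1))
        header[k] = v
    if header.get("popt") != "CP":
        raise ParseError(f"{path}: population type must be CP")
    tags, rows, markers = {}, [], []
    valid = {f"<{t}>" for t in SEG_TYPES}
    for ln, line in enumerate(lines[body_start:], start=body_start + 1):
        if not line.strip():
            continue
        head, _, codes = line.partition("\t")
        parts = head.split()
        if len(parts) < 2 or parts[1] not in valid:
            raise ParseError(f"{path}:{ln}: unknown segregation tag in {head!r}")
        markers.append(parts[0])
        tags[parts[0]] = parts[1].strip("<>")
        rows.append(codes.split())
    n = int(header.get("nind", len(rows[0]) if rows else 0))
    if any(len(r) != n for r in rows):
        bad = next(i for i, r in enumerate(rows) if len(r) != n)
        raise ParseError(f"{path}: locus {markers[bad]} has wrong individual count")
    df = pd.DataFrame(rows, index=markers)
    if int(header.get("nloc", len(df))) != len(df):
        raise ParseError(f"{path}: nloc does not match locus count")
    return header, df, tags


# ---------------------------------------------------------------------------
# map tables and manifests


def write_map_tsv(gmap: GeneticMap, path, distortion: pd.DataFrame | None = None) -> None:
    rows = []
    for lg in gmap.linkage_groups:
        for m, p in zip(lg.markers, lg.positions):
            row = {"marker": m, "lg": lg.lg_id, "pos_cM": round(float(p), 3)}
            if distortion is not None and m in distortion.index:
                row["chi2"] = round(float(distortion.loc[m, "chi2"]), 4)
                row["p"] = float(f"{distortion.loc[m, 'p']:.3e}")
                row["skewed"] = bool(distortion.loc[m, "skewed"])
            rows.append(row)
        for m, reason in lg.unplaced:
            rows.append({"marker": m, "lg": lg.lg_id, "pos_cM": np.nan, "flag": reason})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_map_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"marker", "lg", "pos_cM"}
    if not required <= set(df.columns):
        raise ParseError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    return df


def sha256_of(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(outdir, config: dict, files: list[str]) -> Path:
    """Deterministic run manifest: config echo plus per-file content hashes."""
    outdir = Path(outdir)
    manifest = {
        "config": {k: config[k] for k in sorted(config)},
        "files": {f: sha256_of(outdir / f) for f in sorted(files)},
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
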