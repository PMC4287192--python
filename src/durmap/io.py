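"""Plain-text file formats for every pipeline data type.

Dialect: tab-separated values with mandatory headers, UTF-8, '.' decimal,
``-`` for missing calls; Windows line endings are accepted on read.
cM positions are written with 2 decimals (full precision is kept in
memory). ``read(write(x))`` round-trips every container.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .consensus import ConsensusGroup, ConsensusMap
from .linkage import MISSING, LinkageGroup, SegregationMatrix
from .panel import PanelData

__all__ = [
    "write_segregation",
    "read_segregation",
    "write_map",
    "read_map",
    "write_consensus_map",
    "read_consensus_map",
    "write_panel",
    "read_panel",
    "write_phenotypes",
    "read_phenotypes",
    "write_report",
]

_CALL_OUT = {0: "A", 1: "B", MISSING: "-"}
_CALL_IN = {"A": 0, "B": 1, "-": MISSING}


def write_segregation(seg: SegregationMatrix, path: str | Path) -> None:
    """Markers x lines TSV of A/B/- calls, population type in a comment."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# population_type: {seg.population_type}\n")
        fh.write("marker\t" + "\t".join(seg.lines) + "\n")
        for m, row in zip(seg.markers, seg.calls):
            fh.write(m + "\t" + "\t".join(_CALL_OUT[int(c)] for c in row) + "\n")


def read_segregation(path: str | Path) -> SegregationMatrix:
    path = Path(path)
    text = path.read_text(encoding="utf-8").replace("\r\n", "\n")
    lines = [l for l in text.split("\n") if l.strip()]
    pop_type = "RIL"
    body = []
    for l in lines:
        if l.startswith("#"):
            if "population_type" in l:
                pop_type = l.split(":", 1)[1].strip()
        else:
            body.append(l)
    if not body:
        raise ValidationError(f"{path}: empty segregation file")
    header = body[0].split("\t")
    if header[0] != "marker":
        raise ValidationError(f"{path}: first header column must be 'marker'")
    line_names = tuple(header[1:])
    markers, rows = [], []
    seen = set()
    for ln_no, l in enumerate(body[1:], start=2):
        parts = l.split("\t")
        if len(parts) != len(line_names) + 1:
            raise ValidationError(
                f"{path}:{ln_no}: expected {len(line_names) + 1} columns, got {len(parts)}"
            )
        m = parts[0]
        if m in seen:
            raise ValidationError(f"{path}:{ln_no}: duplicate marker name {m!r}")
        seen.add(m)
        try:
            rows.append([_CALL_IN[c] for c in parts[1:]])
        except KeyError as e:
            raise ValidationError(f"{path}:{ln_no}: unknown genotype code {e.args[0]!r}") from None
        markers.append(m)
    return SegregationMatrix(tuple(markers), line_names, np.array(rows, dtype=np.int8), pop_type)


def write_map(groups: list[LinkageGroup], path: str | Path) -> None:
    """Linkage-group map TSV: marker, group, cM (2 decimals)."""
    rows = [
        (m, g.name, f"{p:.2f}")
        for g in groups
        for m, p in zip(g.markers, g.positions)
    ]
    pd.DataFrame(rows, columns=["marker", "group", "cM"]).to_csv(path, sep="\t", index=False)


def read_map(path: str | Path) -> list[LinkageGroup]:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["marker", "group", "cM"], path)
    _no_duplicates(df["marker"], path)
    out = []
    for name, sub in df.groupby("group", sort=True):
        sub = sub.sort_values("cM", kind="stable")
        pos = sub["cM"].to_numpy(dtype=float)
        out.append(LinkageGroup(str(name), tuple(sub["marker"]), pos - pos[0]))
    return out


def write_consensus_map(cmap: ConsensusMap, path: str | Path) -> None:
    """Consensus map TSV: marker, group, cM, status, sources ('|'-joined)."""
    df = cmap.positions_frame()
    df["cM"] = df["cM"].map(lambda v: f"{v:.2f}")
    df.to_csv(path, sep="\t", index=False)


def read_consensus_map(path: str | Path) -> ConsensusMap:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    _require_columns(df, ["marker", "group", "cM", "status", "sources"], path)
    _no_duplicates(df["marker"], path)
    groups = []
    for name, sub in df.groupby("group", sort=True):
        sub = sub.sort_values("cM", kind="stable")
        pos = sub["cM"].to_numpy(dtype=float)
        groups.append(
            ConsensusGroup(
                str(name),
                tuple(sub["marker"]),
                pos - pos[0],
                tuple(sub["status"]),
                tuple(tuple(s.split("|")) if s else () for s in sub["sources"]),
            )
        )
    return ConsensusMap(tuple(groups))


def write_panel(panel: PanelData, path: str | Path, meta_path: str | Path | None = None) -> None:
    """Accessions x loci TSV of allele indices plus a subpopulation/Q CSV."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("# locus_types: " + ",".join(panel.locus_types) + "\n")
        fh.write("accession\t" + "\t".join(panel.loci) + "\n")
        for a, row in zip(panel.accessions, panel.calls):
            fh.write(a + "\t" + "\t".join("-" if c < 0 else str(int(c)) for c in row) + "\n")
    if meta_path is not None and (panel.subpops is not None or panel.q_matrix is not None):
        meta = pd.DataFrame(index=list(panel.accessions))
        if panel.subpops is not None:
            meta["subpop"] = panel.subpops
        if panel.q_matrix is not None:
            for c in panel.q_matrix.columns:
                meta[f"Q_{c}"] = panel.q_matrix[c]
        meta.index.name = "accession"
        meta.to_csv(meta_path)


def read_panel(path: str | Path, meta_path: str | Path | None = None) -> PanelData:
    path = Path(path)
    text = path.read_text(encoding="utf-8").replace("\r\n", "\n")
    lines = [l for l in text.split("\n") if l.strip()]
    types: tuple[str, ...] | None = None
    body = []
    for l in lines:
        if l.startswith("#"):
            if "locus_types" in l:
                types = tuple(l.split(":", 1)[1].strip().split(","))
        else:
            body.append(l)
    header = body[0].split("\t")
    loci = tuple(header[1:])
    if types is None:
        types = ("SSR",) * len(loci)
    accessions, rows = [], []
    for ln_no, l in enumerate(body[1:], start=2):
        parts = l.split("\t")
        if len(parts) != len(loci) + 1:
            raise ValidationError(f"{path}:{ln_no}: wrong column count")
        accessions.append(parts[0])
        try:
            rows.append([-1 if c == "-" else int(c) for c in parts[1:]])
        except ValueError:
            raise ValidationError(f"{path}:{ln_no}: unknown genotype code") from None
    subpops = q = None
    if meta_path is not None and Path(meta_path).exists():
        meta = pd.read_csv(meta_path, index_col="accession")
        if "subpop" in meta:
            subpops = meta["subpop"]
        qcols = [c for c in meta.columns if c.startswith("Q_")]
        if qcols:
            q = meta[qcols].rename(columns=lambda c: c[2:])
    return PanelData(
        tuple(accessions), loci, np.array(rows, dtype=np.int16), types, subpops, q
    )


def write_phenotypes(phenotypes: pd.DataFrame, path: str | Path) -> None:
    """Long-format CSV: accession, environment, macro_area, latitude, value."""
    cols = ["accession", "environment", "macro_area", "latitude", "value"]
    _require_columns(phenotypes, cols, path)
    phenotypes[cols].to_csv(path, index=False)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["accession", "environment", "macro_area", "latitude", "value"], path)
    return df


def write_report(df: pd.DataFrame, path: str | Path) -> None:
    """Generic report CSV (floats at full precision)."""
    df.to_csv(path, index=False)


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")


def _no_duplicates(series: pd.Series, path) -> None:
    dup = series[series.duplicated()]
    if len(dup):
        raise ValidationError(f"{path}: duplicate marker name {dup.iloc[0]!r}")
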