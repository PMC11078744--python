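"""Readers and writers for the tabular dialects the pipeline exchanges.

All tables are UTF-8, tab-separated with a header row; missing values are
empty cells.  Dialects:

* individuals TSV: id, site, sex [, age_class, age_min, age_max, phase,
  y_haplogroup, mt_haplogroup, snp_count, grave_x, grave_y]
* IBD pairs TSV, per-segment rows: id_a, id_b, chrom, start_cM, end_cM
  [, n_snps, state]; or per-pair summary rows: id_a, id_b, total_ibd1_cM,
  total_ibd2_cM, n_segments, max_ibd_cM [, kinship, degree]
* network edge list: id_a, id_b, weight, same_site
* pedigree file (PLINK-fam-like): id, father_id, mother_id, sex, with a
  unions sidecar table: male_id, female_id, levirate
* calibration curve: '#'-comment lines, then comma- or whitespace-separated
  cal_BP, c14_age_BP, sigma (first three columns used)
* radiocarbon dates TSV: individual_id, c14_age_BP, sigma
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .datamodel import (
    CalibrationCurve,
    FormatError,
    GeneticMap,
    IBDSegment,
    Individual,
    PairRelatedness,
    RadiocarbonDate,
    ValidationError,
    canonical_pair,
    merge_pair_segments,
)
from .pedigree import PedigreeGraph, UnionRecord

PathLike = Union[str, Path, _io.StringIO]


def _read_tsv(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def _require(df: pd.DataFrame, columns: Sequence[str], what: str) -> None:
    for col in columns:
        if col not in df.columns:
            raise FormatError(f"{what}: missing required column {col!r}")


def _opt_int(cell: str) -> Optional[int]:
    return int(float(cell)) if cell.strip() else None


def _opt_float(cell: str) -> Optional[float]:
    return float(cell) if cell.strip() else None


# --------------------------------------------------------------------------
# individuals


def read_individuals(path: PathLike) -> list[Individual]:
    df = _read_tsv(path)
    _require(df, ["id", "site", "sex"], "individuals table")
    if df["id"].duplicated().any():
        dup = df["id"][df["id"].duplicated()].iloc[0]
        raise ValidationError(f"duplicate individual id {dup!r}")
    out = []
    for _, row in df.iterrows():
        age_min = _opt_int(row.get("age_min", ""))
        age_max = _opt_int(row.get("age_max", ""))
        age_range = (age_min, age_max) if age_min is not None and age_max is not None else None
        gx = _opt_float(row.get("grave_x", ""))
        gy = _opt_float(row.get("grave_y", ""))
        out.append(Individual(
            id=row["id"],
            site=row["site"],
            sex=row["sex"].strip() or "unknown",
            age_class=(row.get("age_class", "") or "unknown").strip() or "unknown",
            age_range_years=age_range,
            phase=(row.get("phase", "") or "unknown").strip() or "unknown",
            y_haplogroup=row.get("y_haplogroup", "").strip() or None,
            mt_haplogroup=row.get("mt_haplogroup", "").strip() or None,
            snp_count=_opt_int(row.get("snp_count", "")),
            grave_xy=(gx, gy) if gx is not None and gy is not None else None,
        ))
    return out


def write_individuals(individuals: Iterable[Individual], path: PathLike) -> None:
    rows = []
    for ind in individuals:
        rows.append({
            "id": ind.id,
            "site": ind.site,
            "sex": ind.sex,
            "age_class": ind.age_class,
            "age_min": "" if ind.age_range_years is None else ind.age_range_years[0],
            "age_max": "" if ind.age_range_years is None else ind.age_range_years[1],
            "phase": ind.phase,
            "y_haplogroup": ind.y_haplogroup or "",
            "mt_haplogroup": ind.mt_haplogroup or "",
            "snp_count": "" if ind.snp_count is None else ind.snp_count,
            "grave_x": "" if ind.grave_xy is None else ind.grave_xy[0],
            "grave_y": "" if ind.grave_xy is None else ind.grave_xy[1],
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# IBD pairs

_SEGMENT_COLS = ("id_a", "id_b", "chrom", "start_cM", "end_cM")
_SUMMARY_COLS = ("id_a", "id_b", "total_ibd1_cM", "total_ibd2_cM",
                 "n_segments", "max_ibd_cM")


def read_ibd_pairs(path: PathLike, gmap: Optional[GeneticMap] = None) -> list[PairRelatedness]:
    """Read a pairwise IBD table, auto-detecting segment vs summary dialect."""
    from .relatedness import pair_summary  # local import avoids a cycle

    df = _read_tsv(path)
    if all(c in df.columns for c in _SEGMENT_COLS):
        grouped: dict[tuple[str, str], list[IBDSegment]] = {}
        for _, row in df.iterrows():
            start, end = float(row["start_cM"]), float(row["end_cM"])
            if start >= end:
                raise FormatError(
                    f"pair {row['id_a']}-{row['id_b']} {row['chrom']}: "
                    f"start {start} >= end {end}")
            seg = IBDSegment(
                chrom=row["chrom"], start_cM=start, end_cM=end,
                n_snps=_opt_int(row.get("n_snps", "")),
                state=(row.get("state", "") or "IBD1").strip() or "IBD1",
            )
            if gmap is not None and not seg.within(gmap):
                raise ValidationError(
                    f"segment {seg.chrom}:{seg.start_cM}-{seg.end_cM} exceeds "
                    f"map bounds (map total {gmap.total_cM:.1f} cM)")
            grouped.setdefault(canonical_pair(row["id_a"], row["id_b"]), []).append(seg)
        grouped = merge_pair_segments(grouped)
        out = []
        for (a, b), segs in grouped.items():
            out.append(pair_summary(a, b, segs, gmap))
        return out
    if all(c in df.columns for c in _SUMMARY_COLS):
        records: dict[tuple[str, str], PairRelatedness] = {}
        for _, row in df.iterrows():
            key = canonical_pair(row["id_a"], row["id_b"])
            pr = PairRelatedness(
                id_a=key[0], id_b=key[1],
                total_ibd1_cM=float(row["total_ibd1_cM"]),
                total_ibd2_cM=float(row["total_ibd2_cM"]),
                n_segments=int(float(row["n_segments"])),
                max_ibd_cM=float(row["max_ibd_cM"]),
                kinship=_opt_float(row.get("kinship", "")) or 0.0,
                degree=(row.get("degree", "") or "unrelated").strip() or "unrelated",
            )
            records[key] = pr
        return [records[k] for k in sorted(records)]
    raise FormatError(
        "IBD table matches neither segment dialect "
        f"{_SEGMENT_COLS} nor summary dialect {_SUMMARY_COLS}")


def write_ibd_pairs(pairs: Iterable[PairRelatedness], path: PathLike) -> None:
    """Write per-segment rows (segment dialect)."""
    rows = []
    for pr in pairs:
        for seg in pr.segments:
            rows.append({
                "id_a": pr.id_a, "id_b": pr.id_b, "chrom": seg.chrom,
                "start_cM": seg.start_cM, "end_cM": seg.end_cM,
                "n_snps": "" if seg.n_snps is None else seg.n_snps,
                "state": seg.state,
            })
    pd.DataFrame(rows, columns=["id_a", "id_b", "chrom", "start_cM", "end_cM",
                                "n_snps", "state"]).to_csv(path, sep="\t", index=False)


def write_pair_summaries(pairs: Iterable[PairRelatedness], path: PathLike) -> None:
    """KIN-style classification output: pair, degree, subtype, kinship, summaries."""
    rows = []
    for pr in pairs:
        rows.append({
            "id_a": pr.id_a, "id_b": pr.id_b,
            "total_ibd1_cM": round(pr.total_ibd1_cM, 4),
            "total_ibd2_cM": round(pr.total_ibd2_cM, 4),
            "n_segments": pr.n_segments,
            "max_ibd_cM": round(pr.max_ibd_cM, 4),
            "kinship": round(pr.kinship, 6),
            "degree": pr.degree,
            "subtype": pr.subtype or "",
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# network edges


def write_network_edges(network, path: PathLike) -> None:
    """Edge list: id_a, id_b, weight (max IBD cM), same_site flag."""
    rows = []
    g = network.graph
    for a, b in sorted(tuple(sorted(e)) for e in g.edges):
        rows.append({
            "id_a": a, "id_b": b,
            "weight": g.edges[a, b]["weight"],
            "same_site": int(g.nodes[a].get("site") == g.nodes[b].get("site")),
        })
    pd.DataFrame(rows, columns=["id_a", "id_b", "weight", "same_site"]).to_csv(
        path, sep="\t", index=False)


def read_network_edges(path: PathLike) -> list[tuple[str, str, float]]:
    df = _read_tsv(path)
    _require(df, ["id_a", "id_b", "weight"], "edge list")
    out = []
    for _, row in df.iterrows():
        a, b = canonical_pair(row["id_a"], row["id_b"])
        out.append((a, b, float(row["weight"])))
    return sorted(out)


# --------------------------------------------------------------------------
# pedigree files (PLINK-fam-like dialect + unions sidecar)

_SEX_CODE = {"male": "1", "female": "2", "unknown": "0"}
_SEX_DECODE = {v: k for k, v in _SEX_CODE.items()}


def write_pedigree(ped: PedigreeGraph, fam_path: PathLike,
                   unions_path: Optional[PathLike] = None) -> None:
    rows = []
    for iid in sorted(ped.individuals):
        ind = ped.individuals[iid]
        rows.append({
            "id": iid,
            "father_id": ped.father.get(iid, "0"),
            "mother_id": ped.mother.get(iid, "0"),
            "sex": _SEX_CODE[ind.sex],
        })
    pd.DataFrame(rows, columns=["id", "father_id", "mother_id", "sex"]).to_csv(
        fam_path, sep="\t", index=False)
    if unions_path is not None:
        urows = [{"male_id": u.male_id, "female_id": u.female_id,
                  "levirate": int(u.levirate)} for u in ped.unions]
        pd.DataFrame(urows, columns=["male_id", "female_id", "levirate"]).to_csv(
            unions_path, sep="\t", index=False)


def read_pedigree(fam_path: PathLike, unions_path: Optional[PathLike] = None,
                  site: str = "unknown_site") -> PedigreeGraph:
    df = _read_tsv(fam_path)
    _require(df, ["id", "father_id", "mother_id", "sex"], "pedigree file")
    ped = PedigreeGraph()
    for _, row in df.iterrows():
        ped.add_individual(Individual(
            id=row["id"], site=site, sex=_SEX_DECODE.get(row["sex"], "unknown")))
    for _, row in df.iterrows():
        f = row["father_id"] if row["father_id"] not in ("0", "") else None
        m = row["mother_id"] if row["mother_id"] not in ("0", "") else None
        ped.set_parents(row["id"], f, m)
    if unions_path is not None:
        udf = _read_tsv(unions_path)
        _require(udf, ["male_id", "female_id"], "unions table")
        for _, row in udf.iterrows():
            rec = ped.add_union(row["male_id"], row["female_id"],
                                levirate=bool(int(row.get("levirate", "0") or "0")))
            rec.children = sorted(
                c for c in ped.individuals
                if ped.father.get(c) == rec.male_id and ped.mother.get(c) == rec.female_id)
    ped.validate()
    return ped


# --------------------------------------------------------------------------
# calibration curve and dates


def read_calibration_curve(path: PathLike) -> CalibrationCurve:
    if isinstance(path, _io.StringIO):
        lines = path.getvalue().splitlines()
    else:
        lines = Path(path).read_text().splitlines()
    rows = []
    for line in lines:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").split()
        if len(parts) < 3:
            raise FormatError(f"calibration curve row with <3 columns: {line!r}")
        rows.append((float(parts[0]), float(parts[1]), float(parts[2])))
    if len(rows) < 2:
        raise FormatError("calibration curve needs at least 2 rows")
    arr = np.asarray(rows, dtype=float)
    return CalibrationCurve(arr[:, 0], arr[:, 1], arr[:, 2])


def write_calibration_curve(curve: CalibrationCurve, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("# cal_BP, c14_age_BP, sigma\n")
        for bp, age, sig in zip(curve.cal_bp, curve.c14_age_bp, curve.sigma):
            fh.write(f"{bp:.1f},{age:.2f},{sig:.2f}\n")


def read_dates(path: PathLike) -> list[RadiocarbonDate]:
    df = _read_tsv(path)
    _require(df, ["individual_id", "c14_age_BP", "sigma"], "dates table")
    return [RadiocarbonDate(row["individual_id"], float(row["c14_age_BP"]),
                            float(row["sigma"]))
            for _, row in df.iterrows()]


def write_dates(dates: Iterable[RadiocarbonDate], path: PathLike) -> None:
    rows = [{"individual_id": d.individual_id,
             "c14_age_BP": round(d.c14_age_BP, 1),
             "sigma": round(d.sigma, 1)} for d in dates]
    pd.DataFrame(rows, columns=["individual_id", "c14_age_BP", "sigma"]).to_csv(
        path, sep="\t", index=False)
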