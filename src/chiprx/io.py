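"""Readers and writers for the plain-text interchange formats.

BED (0-based half-open, track/browser/comment lines skipped, columns
beyond 6 ignored), gene-model TSV (gene_id, chrom, start, end, strand),
2-column expression TSV, spike-in factor TSV, and the synthetic-dataset
directory layout with its JSON manifest.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .layout import GenomeLayout


class BedFormatError(ValueError):
    pass


def read_bed(path, keep_extra: bool = False) -> pd.DataFrame:
    """Parse a BED3/BED6 file into a chrom/start/end[/name/score/strand] frame.

    Malformed lines (fewer than 3 fields, non-integer or negative
    coordinates, start >= end) raise :class:`BedFormatError` naming the
    line number.
    """
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    names: list[str] = []
    scores: list[str] = []
    strands: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedFormatError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
            try:
                start = int(fields[1])
                end = int(fields[2])
            except ValueError:
                raise BedFormatError(f"{path}:{lineno}: non-integer coordinates {fields[1]!r}/{fields[2]!r}") from None
            if start < 0:
                raise BedFormatError(f"{path}:{lineno}: negative start coordinate {start}")
            if start >= end:
                raise BedFormatError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            chroms.append(fields[0])
            starts.append(start)
            ends.append(end)
            names.append(fields[3] if len(fields) > 3 else "")
            scores.append(fields[4] if len(fields) > 4 else "0")
            strands.append(fields[5] if len(fields) > 5 else ".")
    df = pd.DataFrame(
        {
            "chrom": pd.Series(chroms, dtype=object),
            "start": pd.Series(starts, dtype=np.int64),
            "end": pd.Series(ends, dtype=np.int64),
            "name": pd.Series(names, dtype=object),
            "score": pd.Series(scores, dtype=object),
            "strand": pd.Series(strands, dtype=object),
        }
    )
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    """Write a BED6 file (missing optional columns filled with defaults)."""
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start"].astype(np.int64),
            "end": df["end"].astype(np.int64),
            "name": df["name"] if "name" in df.columns else ".",
            "score": df["score"] if "score" in df.columns else 0,
            "strand": df["strand"] if "strand" in df.columns else ".",
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_genes_tsv(path) -> pd.DataFrame:
    genes = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str, "strand": str})
    required = {"gene_id", "chrom", "start", "end", "strand"}
    missing = required - set(genes.columns)
    if missing:
        raise ValueError(f"{path}: gene table missing columns {sorted(missing)}")
    return genes


def write_genes_tsv(genes: pd.DataFrame, path) -> None:
    genes.loc[:, ["gene_id", "chrom", "start", "end", "strand"]].to_csv(path, sep="\t", index=False)


def read_expression_tsv(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if "gene_id" not in df.columns or df.shape[1] < 2:
        raise ValueError(f"{path}: expected columns gene_id and expression")
    value_col = [c for c in df.columns if c != "gene_id"][0]
    s = pd.Series(df[value_col].to_numpy(float), index=pd.Index(df["gene_id"], name="gene_id"),
                  name="expression")
    if (s < 0).any():
        raise ValueError(f"{path}: negative expression values")
    return s


def write_expression_tsv(expression: pd.Series, path) -> None:
    expression.rename("expression").rename_axis("gene_id").to_csv(path, sep="\t")


def write_factors_tsv(factors: list, path) -> None:
    pd.DataFrame([f.to_row() for f in factors]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# synthetic dataset directory
# ---------------------------------------------------------------------------

def write_dataset(study, directory, overwrite: bool = False) -> dict:
    """Serialise a SyntheticStudy to a directory of plain-text files.

    Layout: ``layout.yaml``, ``genes.tsv``, ``expression.tsv``,
    ``tiers.tsv``, ``fragments/<sample>.bed``, ``truth/*`` (domain tables
    and condition-specific peak BEDs), and ``manifest.json`` carrying the
    seed, the config, its hash, and per-sample fragment counts.
    Refuses to write into a non-empty directory unless ``overwrite``.
    """
    from dataclasses import asdict

    directory = Path(directory)
    if directory.exists() and any(directory.iterdir()) and not overwrite:
        raise FileExistsError(f"{directory} exists and is not empty (pass overwrite=True)")
    (directory / "fragments").mkdir(parents=True, exist_ok=True)
    (directory / "truth").mkdir(parents=True, exist_ok=True)

    study.layout.to_yaml(directory / "layout.yaml")
    write_genes_tsv(study.genes, directory / "genes.tsv")
    write_expression_tsv(study.expression, directory / "expression.tsv")
    study.tiers.rename_axis("gene_id").to_csv(directory / "tiers.tsv", sep="\t")

    samples = {}
    for sid, frags in study.samples.items():
        rel = f"fragments/{sid}.bed"
        write_bed(frags, directory / rel)
        row = study.sample_table.loc[study.sample_table["sample_id"] == sid].iloc[0]
        samples[sid] = {
            "mark": row["mark"],
            "condition": row["condition"],
            "rep": int(row["rep"]),
            "path": rel,
            "n_fragments": int(len(frags)),
        }

    truth_files = {}
    for mark, dom in study.truth.domains.items():
        safe = mark.replace(".", "")
        rel = f"truth/{safe}.domains.tsv"
        dom.to_csv(directory / rel, sep="\t", index=False)
        truth_files[f"{mark}.domains"] = rel
        for condition in ("control", "k27m"):
            peaks = study.truth.peaks(mark, {"control": "control", "k27m": "condition"}[condition])
            if len(peaks):
                relp = f"truth/peaks_{safe}_{condition}.bed"
                write_bed(peaks, directory / relp)
                truth_files[f"{mark}.peaks.{condition}"] = relp
    write_bed(study.truth.enhancers, directory / "truth/enhancers.bed")
    write_bed(study.truth.poised_enhancers, directory / "truth/poised_enhancers.bed")
    truth_files["enhancers"] = "truth/enhancers.bed"
    truth_files["poised_enhancers"] = "truth/poised_enhancers.bed"
    with open(directory / "truth/retained_domains.json", "w") as fh:
        json.dump({"retained": study.truth.retained_domains,
                   "reduced": study.truth.reduced_domains}, fh, indent=1)
    truth_files["retained_domains"] = "truth/retained_domains.json"

    manifest = {
        "seed": study.config.seed,
        "config": asdict(study.config),
        "config_hash": study.config.config_hash(),
        "samples": samples,
        "truth": truth_files,
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
    return manifest


class Dataset:
    """Read access to a written synthetic dataset directory."""

    def __init__(self, directory):
        self.directory = Path(directory)
        with open(self.directory / "manifest.json") as fh:
            self.manifest = json.load(fh)
        self.layout = GenomeLayout.from_yaml(self.directory / "layout.yaml")

    @property
    def genes(self) -> pd.DataFrame:
        return read_genes_tsv(self.directory / "genes.tsv")

    @property
    def expression(self) -> pd.Series:
        return read_expression_tsv(self.directory / "expression.tsv")

    def fragments(self, sample_id: str) -> pd.DataFrame:
        entry = self.manifest["samples"][sample_id]
        df = read_bed(self.directory / entry["path"])
        df["sample_id"] = sample_id
        return df

    def sample_ids(self, mark: str | None = None, condition: str | None = None) -> list[str]:
        out = []
        for sid, e in sorted(self.manifest["samples"].items()):
            if mark is not None and e["mark"] != mark:
                continue
            if condition is not None and e["condition"] != condition:
                continue
            out.append(sid)
        return out

    def truth_peaks(self, mark: str, condition: str) -> pd.DataFrame:
        key = f"{mark}.peaks.{condition}"
        rel = self.manifest["truth"].get(key)
        if rel is None:
            return pd.DataFrame(columns=["chrom", "start", "end", "name", "score", "strand"])
        return read_bed(self.directory / rel)

    def truth_domains(self, mark: str) -> pd.DataFrame:
        rel = self.manifest["truth"][f"{mark}.domains"]
        return pd.read_csv(self.directory / rel, sep="\t",
                           dtype={"chrom": str, "name": str, "kind": str})

    def truth_bed(self, key: str) -> pd.DataFrame:
        return read_bed(self.directory / self.manifest["truth"][key])

    def retained_reduced(self) -> tuple[list[str], list[str]]:
        with open(self.directory / self.manifest["truth"]["retained_domains"]) as fh:
            d = json.load(fh)
        return d["retained"], d["reduced"]
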