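"""Readers and writers for the interchange formats.

TSV (tab-separated, UTF-8, header row) is the matrix interchange format;
genomic intervals are BED (0-based, half-open) with the name column as the
peak identifier; position weight matrices are JASPAR-style text parsed with
Bio.motifs.  Angles are stored in degrees everywhere on disk.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

__all__ = [
    "read_bed",
    "write_bed",
    "read_matrix",
    "write_matrix",
    "read_pwm",
    "read_tss",
    "write_world",
    "file_sha256",
    "write_manifest",
]


def read_bed(path: str | Path) -> pd.DataFrame:
    """Parse a BED file into chrom/start/end/name, validating half-open
    intervals; malformed lines are reported with their line number."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected at least 3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            name = parts[3] if len(parts) > 3 else f"{parts[0]}:{start}-{end}"
            rows.append((parts[0], start, end, name))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    if df["name"].duplicated().any():
        dupes = df["name"][df["name"].duplicated()].unique()[:5]
        raise ValueError(f"{path}: duplicate interval names, e.g. {list(dupes)}")
    return df


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    df[["chrom", "start", "end", "name"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_matrix(path: str | Path, index_col: int = 0) -> pd.DataFrame:
    """Labeled TSV matrix with unique row and column labels enforced."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    samples = header[:index_col] + header[index_col + 1 :]
    if len(set(samples)) != len(samples):
        raise ValueError(f"{path}: duplicated sample columns")
    df = pd.read_csv(path, sep="\t", index_col=index_col)
    if df.index.duplicated().any():
        raise ValueError(f"{path}: duplicated row labels")
    df.index.name = None
    return df


def write_matrix(df: pd.DataFrame, path: str | Path, label: str = "id") -> None:
    df.to_csv(path, sep="\t", index_label=label)


def read_tss(path: str | Path) -> pd.DataFrame:
    """TSS/gene table: gene, chrom, start, end, strand (TSV with header)."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "chrom", "start", "end", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    bad = ~df["strand"].isin(["+", "-"])
    if bad.any():
        raise ValueError(f"{path}: unknown strand values {df['strand'][bad].unique()}")
    return df


def read_pwm(path: str | Path) -> dict[str, np.ndarray]:
    """JASPAR-format PWMs as probability matrices (4 x width, rows A,C,G,T)."""
    out: dict[str, np.ndarray] = {}
    with open(path) as fh:
        for m in bio_motifs.parse(fh, "jaspar"):
            counts = np.array([m.counts[b] for b in "ACGT"], dtype=float)
            total = counts.sum(axis=0)
            if np.any(total == 0):
                raise ValueError(f"{path}: motif {m.name} has an empty column")
            out[m.name or m.matrix_id] = counts / total
    return out


def write_world(world, outdir: str | Path) -> dict[str, Path]:
    """Write a synthetic world's data files (TSV/BED) plus its truth sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def _put(name: str, writer) -> None:
        p = outdir / name
        writer(p)
        paths[name] = p

    _put("atac.tsv", lambda p: write_matrix(world.atac, p, "peak"))
    _put("rna.tsv", lambda p: write_matrix(world.rna, p, "gene"))
    _put("timing.tsv", lambda p: world.timing.to_frame().to_csv(p, sep="\t", index=False))
    _put("peaks.bed", lambda p: write_bed(world.peak_bed, p))
    _put("tss.tsv", lambda p: world.tss_table.to_csv(p, sep="\t", index=False))
    _put("chip_ip.tsv", lambda p: write_matrix(world.chip_ip, p, "peak"))
    _put("chip_input.tsv", lambda p: write_matrix(world.chip_input, p, "peak"))
    _put(
        "reference_phases.tsv",
        lambda p: world.reference_phases.rename("phase_deg")
        .to_frame()
        .to_csv(p, sep="\t", index_label="gene"),
    )
    if world.atac_treated is not None:
        _put("atac_auxin.tsv", lambda p: write_matrix(world.atac_treated, p, "peak"))
    if world.rna_treated is not None:
        _put("rna_auxin.tsv", lambda p: write_matrix(world.rna_treated, p, "gene"))
    truth = pd.concat(
        [
            world.truth.peak_xy,
            world.truth.amplitude,
            world.truth.phase,
            world.truth.peak_class,
            world.truth.graded_coef,
            world.truth.peak_enrichment.add_prefix("enr_"),
        ],
        axis=1,
    )
    _put("truth_peaks.tsv", lambda p: truth.to_csv(p, sep="\t", index_label="peak"))
    _put(
        "truth_tf_vectors.tsv",
        lambda p: world.truth.tf_vectors.to_csv(p, sep="\t", index_label="tf"),
    )
    return paths


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(outdir: str | Path, stages: list[dict]) -> Path:
    """Run manifest: per stage, its parameters and output file hashes."""
    outdir = Path(outdir)
    manifest = {"stages": stages}
    path = outdir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return path
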