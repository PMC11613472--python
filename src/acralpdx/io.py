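"""Shared table readers/writers, VCF ingestion, and run manifests.

All pipeline tables are tab-delimited text with documented headers and
unit-suffixed columns (``_mm``, ``_uM``, ``_h``, ``_pg``).  Phase images
are 32-bit single-channel TIFF.  Every stage run writes a manifest
(inputs hashed, parameters, seed, package version) sufficient to re-run
it bit-identically.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TABLE_SCHEMAS",
    "read_table",
    "write_table",
    "read_phase_tiff",
    "write_phase_tiff",
    "read_vcf_variants",
    "write_manifest",
]

# schema name -> required columns and dtypes; extra columns are preserved
TABLE_SCHEMAS = {
    "cn_segments": {"sample": str, "locus": str, "copy_number": float},
    "primer_track": {
        "sample": str,
        "gene": str,
        "position": int,
        "fold_change": float,
    },
    "tumor_measurements": {
        "model": str,
        "animal": str,
        "arm": str,
        "day": float,
        "a_mm": float,
        "b_mm": float,
    },
    "cell_mass_tracks": {
        "culture": str,
        "drug": str,
        "dose_uM": float,
        "cell": str,
        "time_h": float,
        "mass_pg": float,
    },
    "variants": {
        "sample": str,
        "gene": str,
        "hgvs": str,
        "allele_frequency": float,
        "alt_obs": int,
        "unique_alt_obs": int,
        "depth": int,
        "vaf": float,
    },
    "ihc": {
        "model": str,
        "arm": str,
        "stain": str,
        "value": float,
    },
    "drift_scores": {
        "model": str,
        "passage_class": str,
        "rater": str,
        "score": int,
    },
}


def read_table(path, schema: str) -> pd.DataFrame:
    """Read and validate a tab-delimited pipeline table.

    Columns required by ``schema`` are type-coerced; a cell that fails
    coercion raises with the offending row and column named.  Extra
    columns pass through untouched.
    """
    spec = TABLE_SCHEMAS[schema]
    df = pd.read_csv(path, sep="\t")
    missing = set(spec) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    for col, dtype in spec.items():
        try:
            df[col] = df[col].astype(dtype)
        except (ValueError, TypeError):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()]
            row = int(bad[0]) if len(bad) else "?"
            raise ValueError(
                f"{path}: cannot coerce column {col!r} to {dtype.__name__} "
                f"(first bad row {row})"
            ) from None
    return df


def write_table(df: pd.DataFrame, path, schema: str | None = None) -> None:
    """Write a pipeline table as tab-delimited text (schema-checked)."""
    if schema is not None:
        missing = set(TABLE_SCHEMAS[schema]) - set(df.columns)
        if missing:
            raise ValueError(f"missing columns for {schema}: {sorted(missing)}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def write_phase_tiff(image: np.ndarray, path) -> None:
    """Write a phase map as 32-bit single-channel TIFF."""
    import tifffile

    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))


def read_phase_tiff(path) -> np.ndarray:
    import tifffile

    img = tifffile.imread(path)
    if img.ndim != 2:
        raise ValueError(f"{path}: expected single-channel 2-D phase map")
    return np.asarray(img, dtype=np.float32)


# default mapping from VCF fields to VariantRecord columns; INFO keys are
# caller-specific, hence configurable
DEFAULT_VCF_MAPPING = {
    "allele_frequency": ("INFO", "AF"),
    "alt_obs": ("INFO", "AO"),
    "unique_alt_obs": ("INFO", "UAO"),
    "depth": ("INFO", "DP"),
    "vaf": ("INFO", "VAF"),
    "gene": ("INFO", "GENE"),
}


def read_vcf_variants(path, mapping: dict | None = None) -> pd.DataFrame:
    """Ingest variants from a VCF into the panel variant-table schema.

    ``mapping`` maps output columns to ``("INFO", key)`` sources; sample
    id is the single VCF sample (or the file stem when absent).
    """
    import pysam

    mapping = {**DEFAULT_VCF_MAPPING, **(mapping or {})}
    vcf = pysam.VariantFile(str(path))
    sample = list(vcf.header.samples)[0] if len(vcf.header.samples) else Path(path).stem
    rows = []
    for rec in vcf:
        row = {
            "sample": sample,
            "hgvs": f"{rec.chrom}:g.{rec.pos}{rec.ref}>{(rec.alts or ('?',))[0]}",
        }
        for col, (src, key) in mapping.items():
            if src != "INFO":
                raise ValueError(f"unsupported mapping source {src!r}")
            val = rec.info.get(key)
            if isinstance(val, tuple):
                val = val[0]
            row[col] = val
        rows.append(row)
    vcf.close()
    return pd.DataFrame(rows)


def _hash_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, stage: str, params: dict, seed: int | None,
                   inputs=(), outputs=()) -> Path:
    """Write a JSON run manifest with hashed inputs/outputs."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "stage": stage,
        "package_version": __version__,
        "seed": seed,
        "params": params,
        "inputs": {str(p): _hash_file(p) for p in inputs},
        "outputs": {str(p): _hash_file(p) for p in outputs},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return path
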