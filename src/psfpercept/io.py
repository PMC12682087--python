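"""File formats: long-format ratings CSVs, TSV matrices, plain PGM rasters.

All writers round-trip through the matching readers. Malformed input rows
are rejected with their line numbers — never silently coerced.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .agreement import LikertResponseSet
from .mds import SimilarityStudy
from .optics import ImageRaster

LIKERT_COLUMNS = ["rater_id", "image_id", "image_type", "descriptor_index", "response"]
SIMILARITY_COLUMNS = ["rater_id", "image_a", "image_b", "block", "rating"]


def _maybe_int(series: pd.Series) -> pd.Series:
    """Convert string identifiers back to integers where possible."""
    try:
        return series.astype(int)
    except (TypeError, ValueError):
        return series


def _read_strict_csv(path, columns: list[str], int_cols: dict[str, tuple[int, int]]):
    """Read a CSV requiring exactly the given columns; integer columns are
    validated row-by-row so errors carry line numbers (header = line 1)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != columns:
        raise ValueError(
            f"{path}: expected columns {columns}, found {list(df.columns)}"
        )
    for col, (lo, hi) in int_cols.items():
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() | (parsed != parsed.astype("Int64").astype(float)) | ~parsed.between(lo, hi)
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 zero-based
            raise ValueError(
                f"{path}: invalid value {df[col][bad.idxmax()]!r} in column "
                f"{col!r} at line {line} (expected integer in {lo}..{hi})"
            )
        df[col] = parsed.astype(int)
    return df


# ---------------------------------------------------------------------------
# Likert responses
# ---------------------------------------------------------------------------


def write_likert_csv(
    path, drawn: LikertResponseSet, geometric: LikertResponseSet | None = None
) -> None:
    frames = []
    for lrs in (drawn, geometric):
        if lrs is None:
            continue
        df = lrs.responses.copy()
        df["image_type"] = lrs.image_type
        frames.append(df[LIKERT_COLUMNS])
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_likert_csv(path) -> dict[str, LikertResponseSet]:
    """Read a combined Likert CSV; returns response sets keyed by image type."""
    df = _read_strict_csv(
        path,
        LIKERT_COLUMNS,
        {"descriptor_index": (0, 12), "response": (1, 5)},
    )
    bad = ~df["image_type"].isin(["drawn", "geometric"])
    if bad.any():
        raise ValueError(
            f"{path}: unknown image_type at line {int(bad.idxmax()) + 2}"
        )
    df["image_id"] = _maybe_int(df["image_id"])
    out = {}
    for image_type, sub in df.groupby("image_type"):
        out[image_type] = LikertResponseSet(
            sub.drop(columns="image_type").reset_index(drop=True),
            image_type=str(image_type),
        )
    return out


# ---------------------------------------------------------------------------
# Similarity ratings
# ---------------------------------------------------------------------------


def write_similarity_csv(path, study: SimilarityStudy) -> None:
    study.ratings[SIMILARITY_COLUMNS].to_csv(path, index=False)


def read_similarity_csv(path) -> SimilarityStudy:
    df = _read_strict_csv(path, SIMILARITY_COLUMNS, {"rating": (1, 10)})
    for col in ("image_a", "image_b"):
        df[col] = _maybe_int(df[col])
    return SimilarityStudy(df)


# ---------------------------------------------------------------------------
# Matrices and configurations
# ---------------------------------------------------------------------------


def write_matrix_tsv(path, matrix, index=None) -> None:
    pd.DataFrame(np.asarray(matrix), index=index, columns=index).to_csv(
        path, sep="\t"
    )


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_coords_tsv(path, coords: np.ndarray, items=None) -> None:
    coords = np.asarray(coords)
    cols = [f"dim{i + 1}" for i in range(coords.shape[1])]
    pd.DataFrame(coords, index=items, columns=cols).to_csv(path, sep="\t")


def read_coords_tsv(path) -> np.ndarray:
    return pd.read_csv(path, sep="\t", index_col=0).to_numpy()


# ---------------------------------------------------------------------------
# Rasters: plain (P2) PGM with a JSON sidecar for the angular scale
# ---------------------------------------------------------------------------

_PGM_MAXVAL = 65535


def write_pgm(path, raster: ImageRaster) -> None:
    """Write a plain-text (P2) PGM plus a ``<name>.json`` sidecar holding
    polarity and arcmin-per-pixel scale; lossless at 16-bit quantization."""
    path = Path(path)
    levels = np.round(raster.pixels * _PGM_MAXVAL).astype(int)
    h, w = levels.shape
    with open(path, "w") as fh:
        fh.write(f"P2\n{w} {h}\n{_PGM_MAXVAL}\n")
        for row in levels:
            fh.write(" ".join(map(str, row)) + "\n")
    sidecar = {
        "polarity": raster.polarity,
        "arcmin_per_pixel": raster.arcmin_per_pixel,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def read_pgm(path) -> ImageRaster:
    path = Path(path)
    tokens: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0]
            tokens.extend(line.split())
    if not tokens or tokens[0] != "P2":
        raise ValueError(f"{path}: not a plain (P2) PGM file")
    w, h, maxval = int(tokens[1]), int(tokens[2]), int(tokens[3])
    data = np.array(tokens[4 : 4 + w * h], dtype=float).reshape(h, w) / maxval
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
    else:
        meta = {"polarity": "light_on_dark", "arcmin_per_pixel": 1.0}
    return ImageRaster(data, meta["polarity"], meta["arcmin_per_pixel"])


def write_png(path, raster: ImageRaster) -> None:
    from PIL import Image

    arr = np.round(raster.pixels * 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)


def write_psf_counts_tsv(path, psf) -> None:
    header = (
        f"# bins={psf.bins} bin_width_arcmin={psf.bin_width} "
        f"half_width_arcmin={psf.half_width} rays_total={psf.rays_total} "
        f"out_of_field={psf.out_of_field}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, psf.counts, fmt="%d", delimiter="\t")


def read_psf_counts_tsv(path):
    """Read back a PSF counts TSV written by :func:`write_psf_counts_tsv`."""
    from .optics import GeometricPSF

    with open(path) as fh:
        header = fh.readline()
        counts = np.loadtxt(fh, dtype=np.int64, delimiter="\t")
    meta = dict(
        token.split("=") for token in header.lstrip("# ").split() if "=" in token
    )
    return GeometricPSF(
        counts=counts,
        bin_width=float(meta["bin_width_arcmin"]),
        half_width=float(meta["half_width_arcmin"]),
        rays_total=int(meta["rays_total"]),
        out_of_field=int(meta["out_of_field"]),
    )


def write_json_report(path, payload: dict, seed=None, config_hash=None) -> None:
    """JSON report writer stamping provenance (seed, config hash) into the
    header of every output."""
    out = {"_meta": {"seed": seed, "config_hash": config_hash}}
    out.update(payload)
    Path(path).write_text(json.dumps(out, indent=2, default=_jsonify, sort_keys=True))


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if hasattr(obj, "__fraction__") or type(obj).__name__ == "Fraction":
        return str(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
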