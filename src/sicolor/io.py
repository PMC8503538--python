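"""Reading and writing the pipeline's file formats.

Metadata is a CSV of individual_id, population, sex, svl_mm, capture_date
(ISO-8601); pixels come either as a long CSV (individual_id, R, G, B) or as
8-bit RGB images with a same-size single-channel mask (nonzero = region of
interest).  Spectra, scores and posterior draws are written as plain CSV,
summaries as JSON.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .cosinor import ADULT_MIN_SVL, IndividualRecord, PosteriorDraws
from .spectra import ColourSpectrum, PixelSet

__all__ = [
    "read_metadata",
    "day_of_year",
    "read_pixel_table",
    "read_image_pixels",
    "write_spectra_csv",
    "read_spectra_csv",
    "write_scores_csv",
    "write_loadings_csv",
    "write_draws_csv",
    "write_metadata_csv",
    "write_pixel_table",
    "config_hash",
]

log = logging.getLogger("sicolor")

_REQUIRED_COLUMNS = ("individual_id", "population", "sex", "svl_mm", "capture_date")


def day_of_year(date: dt.date) -> int:
    """Day-of-year on a fixed 365-day basis (1 = 1 January).

    In leap years, 29 February maps to day 60 with a warning and later
    dates are shifted back one day, so a given calendar date always maps
    to the same day number.
    """
    doy = date.timetuple().tm_yday
    if not (date.year % 4 == 0 and (date.year % 100 != 0 or date.year % 400 == 0)):
        return doy
    if date.month == 2 and date.day == 29:
        warnings.warn("29 February mapped to day 60 on the 365-day basis")
        return 60
    return doy - 1 if doy > 60 else doy


def read_metadata(path) -> list[IndividualRecord]:
    """Load the individual table, excluding juveniles (SVL < 50 mm).

    Dates must be ISO-8601; sex labels are normalized (m/M/male -> male).
    Duplicate individual ids and missing columns are errors.
    """
    df = pd.read_csv(path)
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"metadata is missing required column {col!r}")
    dup = df["individual_id"].astype(str).duplicated()
    if dup.any():
        raise ValueError(f"duplicate individual_id: {df['individual_id'][dup].iloc[0]!r}")
    records, excluded = [], 0
    for idx, row in df.iterrows():
        svl = float(row["svl_mm"])
        if svl < ADULT_MIN_SVL:
            excluded += 1
            continue
        try:
            date = dt.date.fromisoformat(str(row["capture_date"]).strip())
        except ValueError as exc:
            raise ValueError(f"unparseable capture_date at row {idx + 1}: "
                             f"{row['capture_date']!r}") from exc
        score = float(row["pc1_score"]) if "pc1_score" in df.columns else None
        records.append(IndividualRecord(
            id=str(row["individual_id"]),
            population=str(row["population"]),
            sex=str(row["sex"]),
            svl=svl,
            day=day_of_year(date),
            score=score,
        ))
    if excluded:
        log.info("excluded %d juvenile record(s) with SVL < %g mm", excluded, ADULT_MIN_SVL)
    return records


def read_pixel_table(path) -> list[PixelSet]:
    """Long CSV (individual_id, R, G, B) -> one PixelSet per individual."""
    df = pd.read_csv(path)
    for col in ("individual_id", "R", "G", "B"):
        if col not in df.columns:
            raise ValueError(f"pixel table is missing required column {col!r}")
    out = []
    for ind, grp in df.groupby("individual_id", sort=False):
        out.append(PixelSet(str(ind), grp[["R", "G", "B"]].to_numpy(dtype=int)))
    return out


def read_image_pixels(image_path, mask_path, individual_id: str) -> PixelSet:
    """Extract ROI pixels from an 8-bit RGB image and a same-size mask.

    Mask is single-channel; nonzero marks the region of interest.
    """
    from PIL import Image

    img = np.asarray(Image.open(image_path).convert("RGB"))
    mask = np.asarray(Image.open(mask_path).convert("L"))
    if img.shape[:2] != mask.shape:
        raise ValueError("image and mask dimensions differ")
    pixels = img[mask > 0]
    if pixels.size == 0:
        raise ValueError("mask selects no pixels")
    return PixelSet(individual_id, pixels.astype(int))


def write_spectra_csv(spectra: list[ColourSpectrum], path) -> None:
    """One row per individual; columns are bin midpoints; channel recorded per row."""
    if not spectra:
        raise ValueError("no spectra to write")
    mids = spectra[0].midpoints
    df = pd.DataFrame(
        np.vstack([s.frequencies for s in spectra]),
        columns=[f"{m:.6g}" for m in mids],
    )
    df.insert(0, "channel", [s.channel for s in spectra])
    df.insert(0, "individual_id", [s.individual_id for s in spectra])
    df.to_csv(path, index=False)


def read_spectra_csv(path) -> list[ColourSpectrum]:
    """Inverse of :func:`write_spectra_csv` (uniform bins reconstructed)."""
    df = pd.read_csv(path)
    mids = np.array([float(c) for c in df.columns[2:]])
    width = mids[1] - mids[0]
    edges = np.concatenate([mids - width / 2, [mids[-1] + width / 2]])
    # snap to the exact channel range to undo float round-tripping
    edges[0] = round(edges[0], 9)
    out = []
    for _, row in df.iterrows():
        out.append(ColourSpectrum(
            str(row["individual_id"]), str(row["channel"]),
            edges, row.iloc[2:].to_numpy(dtype=float),
        ))
    return out


def write_scores_csv(individual_ids, channel: str, scores, path) -> None:
    pd.DataFrame({
        "individual_id": individual_ids,
        "channel": channel,
        "pc1_score": np.asarray(scores, dtype=float),
    }).to_csv(path, index=False)


def write_loadings_csv(pca_result, path) -> None:
    mids = 0.5 * (pca_result.bin_edges[:-1] + pca_result.bin_edges[1:])
    df = pd.DataFrame(pca_result.loadings, columns=[f"{m:.6g}" for m in mids])
    df.insert(0, "explained_fraction", pca_result.explained_fraction)
    df.insert(0, "component", np.arange(1, len(df) + 1))
    df.to_csv(path, index=False)


def write_draws_csv(draws: PosteriorDraws, path) -> None:
    """Long format: chain, iteration, parameter, value."""
    frames = []
    for name, arr in draws.params.items():
        n_chain, n_iter = arr.shape
        frames.append(pd.DataFrame({
            "chain": np.repeat(np.arange(n_chain), n_iter),
            "iteration": np.tile(np.arange(n_iter), n_chain),
            "parameter": name,
            "value": arr.reshape(-1),
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_metadata_csv(records, path, base_year: int = 2019) -> None:
    """Records -> the metadata CSV format the pipeline reads."""
    rows = []
    for r in records:
        date = dt.date(base_year, 1, 1) + dt.timedelta(days=int(r.day) - 1)
        row = {"individual_id": r.id, "population": r.population, "sex": r.sex,
               "svl_mm": r.svl, "capture_date": date.isoformat()}
        if r.score is not None:
            row["pc1_score"] = r.score
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_pixel_table(pixel_sets, path) -> None:
    frames = [
        pd.DataFrame({"individual_id": ps.individual_id,
                      "R": ps.pixels[:, 0], "G": ps.pixels[:, 1], "B": ps.pixels[:, 2]})
        for ps in pixel_sets
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def config_hash(config: dict) -> str:
    """Stable short hash of a config dict, embedded in every output."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
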