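"""Strand-specific probe tracks: loading, replicate averaging, binning and
3'-end-anchored window extraction.

A probe track holds, for one (chromosome, strand), the sorted probe-center
positions and one log2-intensity array per sample. Binning averages probe
intensities over fixed-width windows (25 bp by default); a probe belongs to
the bin containing its center. Empty bins are reported as missing (NaN mean,
zero count), never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .annotation import Feature, three_prime_end

TrackKey = Tuple[str, str]  # (chrom, strand)


class TrackError(ValueError):
    """Malformed probe-track input."""


@dataclass
class ProbeTrack:
    chrom: str
    strand: str
    positions: np.ndarray  # strictly increasing probe centers, int
    samples: Dict[str, np.ndarray]  # sample id -> log2 intensities

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.positions.ndim != 1:
            raise TrackError("positions must be 1-D")
        if len(self.positions) and np.any(np.diff(self.positions) <= 0):
            raise TrackError(
                f"track ({self.chrom},{self.strand}): positions must be "
                "strictly increasing"
            )
        for sid, arr in self.samples.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != self.positions.shape:
                raise TrackError(
                    f"track ({self.chrom},{self.strand}) sample {sid!r}: "
                    f"{arr.shape[0] if arr.ndim == 1 else '?'} intensities for "
                    f"{len(self.positions)} positions (ragged track)"
                )
            if not np.all(np.isfinite(arr)):
                raise TrackError(
                    f"track ({self.chrom},{self.strand}) sample {sid!r}: "
                    "non-finite intensity (missing probes must be absent, not NaN)"
                )
            self.samples[sid] = arr

    @property
    def key(self) -> TrackKey:
        return (self.chrom, self.strand)

    @property
    def sample_ids(self) -> List[str]:
        return list(self.samples)


@dataclass
class BinnedProfile:
    """Fixed-width bin means anchored at a feature's 3' end.

    ``offsets`` are bin indices relative to the anchor in the direction of
    transcription: offset 0 is the first bin past the 3' end, negative
    offsets lie inside the gene. Bins with ``n_probes == 0`` are missing
    (NaN mean). ``truncated`` flags a window clipped at a chromosome edge.
    """

    feature_id: str
    bin_width: int
    offsets: np.ndarray
    means: np.ndarray
    n_probes: np.ndarray
    truncated: bool = False

    def __post_init__(self) -> None:
        if len(self.offsets) and np.any(np.diff(self.offsets) != 1):
            raise ValueError("offsets must be contiguous")


def read_probe_tracks(path: str) -> Dict[TrackKey, ProbeTrack]:
    """Read a probe-track TSV into one ProbeTrack per (chrom, strand).

    Expected columns: ``chrom``, ``strand``, ``position``, then one numeric
    column per sample. Rows may be in any order; duplicate positions within a
    (chrom, strand) are an error.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = ["chrom", "strand", "position"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TrackError(f"{path}: missing columns {missing}")
    sample_cols = [c for c in df.columns if c not in required]
    if not sample_cols:
        raise TrackError(f"{path}: no sample columns")
    for c in sample_cols:
        if not pd.api.types.is_numeric_dtype(df[c]):
            raise TrackError(f"{path}: non-numeric intensity in column {c!r}")
        if df[c].isna().any():
            pos = df.loc[df[c].isna(), "position"].iloc[0]
            raise TrackError(
                f"{path}: sample {c!r} missing at position {pos} (ragged track)"
            )
    tracks: Dict[TrackKey, ProbeTrack] = {}
    for (chrom, strand), grp in df.groupby(["chrom", "strand"], sort=True):
        grp = grp.sort_values("position")
        dup = grp["position"].duplicated()
        if dup.any():
            p = grp.loc[dup, "position"].iloc[0]
            raise TrackError(
                f"{path}: duplicate probe at ({chrom},{strand}) position {p}"
            )
        tracks[(chrom, strand)] = ProbeTrack(
            chrom=str(chrom),
            strand=str(strand),
            positions=grp["position"].to_numpy(),
            samples={c: grp[c].to_numpy(dtype=float) for c in sample_cols},
        )
    return tracks


def write_probe_tracks(
    tracks: Dict[TrackKey, ProbeTrack], path: str, float_fmt: str = "%.6f"
) -> None:
    frames = []
    for (chrom, strand), tr in sorted(tracks.items()):
        d = {"chrom": chrom, "strand": strand, "position": tr.positions}
        d.update(tr.samples)
        frames.append(pd.DataFrame(d))
    pd.concat(frames, ignore_index=True).to_csv(
        path, sep="\t", index=False, float_format=float_fmt
    )


def average_replicates(track: ProbeTrack, sample_ids: Sequence[str]) -> np.ndarray:
    """Per-probe arithmetic mean over the named samples."""
    unknown = [s for s in sample_ids if s not in track.samples]
    if unknown:
        raise TrackError(f"unknown sample id(s) {unknown} in track {track.key}")
    if not sample_ids:
        raise TrackError("no sample ids given")
    return np.mean([track.samples[s] for s in sample_ids], axis=0)


def bin_signal(
    track: ProbeTrack,
    values: np.ndarray,
    region_start: int,
    region_end: int,
    bin_width: int = 25,
) -> Tuple[np.ndarray, np.ndarray]:
    """Mean intensity and probe count per bin over [region_start, region_end).

    Bin b covers ``[region_start + b*w, region_start + (b+1)*w)``; a probe is
    assigned to the bin containing its center. Returns (means, counts) with
    NaN means for empty bins.
    """
    if region_end <= region_start:
        raise ValueError(f"empty region [{region_start}, {region_end})")
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    values = np.asarray(values, dtype=float)
    if values.shape != track.positions.shape:
        raise TrackError("values not aligned to track positions")
    n_bins = -(-(region_end - region_start) // bin_width)
    in_region = (track.positions >= region_start) & (track.positions < region_end)
    pos = track.positions[in_region]
    val = values[in_region]
    idx = (pos - region_start) // bin_width
    counts = np.bincount(idx, minlength=n_bins).astype(np.int64)
    sums = np.bincount(idx, weights=val, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return means, counts


def aligned_window(
    f: Feature,
    track: ProbeTrack,
    values: np.ndarray,
    upstream_bp: int,
    downstream_bp: int,
    bin_width: int = 25,
    chrom_length: Optional[int] = None,
) -> BinnedProfile:
    """3'-end-anchored binned profile oriented in transcription direction.

    Offset 0 is the first bin past the 3' anchor; offset -1 the last bin
    inside the gene. On the - strand, genomic bins run toward decreasing
    coordinates and the offset axis is reversed, so the profile is strand
    symmetric. Bins extending past the chromosome (or below 0) are flagged
    missing and the profile marked truncated.
    """
    if track.strand != f.strand or track.chrom != f.chrom:
        raise TrackError(
            f"feature {f.id} on ({f.chrom},{f.strand}) does not match track "
            f"{track.key}"
        )
    if upstream_bp % bin_width or downstream_bp % bin_width:
        raise ValueError("upstream_bp and downstream_bp must be bin_width multiples")
    anchor = three_prime_end(f)
    n_up = upstream_bp // bin_width
    n_down = downstream_bp // bin_width
    offsets = np.arange(-n_up, n_down)
    if f.strand == "+":
        # genomic bin for offset o: [anchor + o*w, anchor + (o+1)*w)
        gstarts = anchor + offsets * bin_width
    else:
        # genomic bin for offset o: [anchor - (o+1)*w, anchor - o*w)
        gstarts = anchor - (offsets + 1) * bin_width
    gends = gstarts + bin_width
    lo, hi = int(gstarts.min()), int(gends.max())
    # Bin on the genomic grid anchored at lo (probe positions are never
    # negative, so a lo < 0 grid start is harmless), then map grid bins onto
    # transcription-direction offsets.
    values = np.asarray(values, dtype=float)
    if values.shape != track.positions.shape:
        raise TrackError("values not aligned to track positions")
    pos = track.positions
    mask = (pos >= lo) & (pos < hi)
    idx = (pos[mask] - lo) // bin_width
    n_grid = (hi - lo) // bin_width
    grid_counts = np.bincount(idx, minlength=n_grid).astype(np.int64)
    grid_sums = np.bincount(idx, weights=values[mask], minlength=n_grid)
    j = (gstarts - lo) // bin_width
    counts = grid_counts[j]
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, grid_sums[j] / np.maximum(counts, 1), np.nan)
    in_genome = gstarts >= 0
    if chrom_length is not None:
        in_genome &= gends <= chrom_length
    means[~in_genome] = np.nan
    counts[~in_genome] = 0
    return BinnedProfile(
        feature_id=f.id,
        bin_width=bin_width,
        offsets=offsets,
        means=means,
        n_probes=counts,
        truncated=bool(np.any(~in_genome)),
    )


def normalize_tracks(
    tracks: Dict[TrackKey, ProbeTrack], method: str = "median_center"
) -> Dict[TrackKey, ProbeTrack]:
    """Per-sample normalization across all tracks.

    ``median_center`` subtracts each sample's global median log2 intensity
    (a deliberately simple stand-in for array normalization); ``none`` is
    the identity.
    """
    if not tracks:
        raise TrackError("no tracks to normalize")
    if method == "none":
        return tracks
    if method != "median_center":
        raise ValueError(f"unknown normalization method {method!r}")
    sample_ids = next(iter(tracks.values())).sample_ids
    medians = {
        s: float(np.median(np.concatenate([t.samples[s] for t in tracks.values()])))
        for s in sample_ids
    }
    out: Dict[TrackKey, ProbeTrack] = {}
    for key, tr in tracks.items():
        out[key] = ProbeTrack(
            chrom=tr.chrom,
            strand=tr.strand,
            positions=tr.positions.copy(),
            samples={s: tr.samples[s] - medians[s] for s in tr.samples},
        )
    return out


def profile_to_bedgraph(p: BinnedProfile, f: Feature) -> pd.DataFrame:
    """One BEDgraph row per non-missing bin, in genomic coordinates."""
    anchor = three_prime_end(f)
    if f.strand == "+":
        starts = anchor + p.offsets * p.bin_width
    else:
        starts = anchor - (p.offsets + 1) * p.bin_width
    ok = np.isfinite(p.means)
    df = pd.DataFrame(
        {
            "chrom": f.chrom,
            "start": starts[ok],
            "end": starts[ok] + p.bin_width,
            "value": p.means[ok],
        }
    )
    return df.sort_values("start").reset_index(drop=True)


def profile_to_frame(p: BinnedProfile) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature_id": p.feature_id,
            "offset_bin": p.offsets,
            "offset_bp": p.offsets * p.bin_width,
            "mean": p.means,
            "n_probes": p.n_probes,
        }
    )
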