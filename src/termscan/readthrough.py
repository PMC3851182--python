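"""Readthrough calling at transcript 3' ends.

The rule: average mutant and wildtype probe intensities (replicates first)
over 25 bp bins downstream of each feature's 3' end, and score readthrough
positive when the mutant-minus-wildtype difference exceeds 0.6 log2 units in
at least 4 of the 6 bins covering the first 150 bp. Features whose 3' end
lies less than 150 bp upstream of the next same-strand transcript are
excluded, because trailing signal there cannot be attributed to readthrough.

All thresholds live in :class:`ReadthroughParams`; inequalities follow the
rule's literal wording: the 0.6 difference is strict (0.6 exactly does not
count), "at least 4" is non-strict, and the exclusion at <150 bp is strict
(a neighbor at exactly 150 bp is kept).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .annotation import Feature, GenomeAnnotation, downstream_neighbor_distance
from .tiling import BinnedProfile, ProbeTrack, TrackKey, aligned_window, average_replicates


@dataclass(frozen=True)
class ReadthroughParams:
    bin_width: int = 25
    window_bp: int = 150
    n_bins: int = 6
    min_bins_above: int = 4
    diff_threshold: float = 0.6  # log2 units, strict
    exclusion_distance: int = 150  # bp, strict

    def __post_init__(self) -> None:
        if self.n_bins * self.bin_width != self.window_bp:
            raise ValueError(
                f"n_bins*bin_width = {self.n_bins * self.bin_width} "
                f"!= window_bp = {self.window_bp}"
            )
        if not (1 <= self.min_bins_above <= self.n_bins):
            raise ValueError("require 1 <= min_bins_above <= n_bins")
        if self.diff_threshold <= 0:
            raise ValueError("diff_threshold must be > 0")


@dataclass
class ReadthroughCall:
    feature_id: str
    feature_class: str
    diffs: np.ndarray  # mutant bin mean - wildtype bin mean, NaN = missing
    n_above: int
    excluded: bool
    exclusion_reason: str  # neighbor_too_close | missing_bins | none
    call: bool


def downstream_diffs(
    f: Feature,
    mut_track: ProbeTrack,
    wt_track: ProbeTrack,
    params: ReadthroughParams = ReadthroughParams(),
    mut_samples: Optional[Sequence[str]] = None,
    wt_samples: Optional[Sequence[str]] = None,
    chrom_length: Optional[int] = None,
) -> np.ndarray:
    """Mutant-minus-wildtype bin means for the n_bins downstream bins.

    Replicates named in ``mut_samples``/``wt_samples`` (default: all samples
    in each track) are averaged per probe before binning. A bin missing in
    either condition yields NaN.
    """
    mut_samples = list(mut_samples or mut_track.sample_ids)
    wt_samples = list(wt_samples or wt_track.sample_ids)
    mut_vals = average_replicates(mut_track, mut_samples)
    wt_vals = average_replicates(wt_track, wt_samples)
    kw = dict(
        upstream_bp=0,
        downstream_bp=params.window_bp,
        bin_width=params.bin_width,
        chrom_length=chrom_length,
    )
    mut = aligned_window(f, mut_track, mut_vals, **kw)
    wt = aligned_window(f, wt_track, wt_vals, **kw)
    return mut.means - wt.means


def call_readthrough(
    f: Feature,
    diffs: np.ndarray,
    neighbor_distance: Optional[int],
    params: ReadthroughParams = ReadthroughParams(),
) -> ReadthroughCall:
    """Apply the thresholding rule to one feature's downstream differences.

    Exclusion (in order of precedence): a downstream neighbor closer than
    ``exclusion_distance``; or so many missing bins that ``min_bins_above``
    can no longer be reached. Missing bins never count as above threshold.
    """
    diffs = np.asarray(diffs, dtype=float)
    if len(diffs) != params.n_bins:
        raise ValueError(f"expected {params.n_bins} diffs, got {len(diffs)}")
    n_missing = int(np.sum(~np.isfinite(diffs)))
    n_above = int(np.sum(diffs[np.isfinite(diffs)] > params.diff_threshold))
    if neighbor_distance is not None and neighbor_distance < params.exclusion_distance:
        excluded, reason = True, "neighbor_too_close"
    elif n_missing > params.n_bins - params.min_bins_above:
        excluded, reason = True, "missing_bins"
    else:
        excluded, reason = False, "none"
    return ReadthroughCall(
        feature_id=f.id,
        feature_class=f.feature_class,
        diffs=diffs,
        n_above=n_above,
        excluded=excluded,
        exclusion_reason=reason,
        call=(not excluded) and n_above >= params.min_bins_above,
    )


def call_all(
    ann: GenomeAnnotation,
    tracks: Dict[TrackKey, ProbeTrack],
    mut_samples: Sequence[str],
    wt_samples: Sequence[str],
    params: ReadthroughParams = ReadthroughParams(),
    classes: Optional[Sequence[str]] = None,
    neighbor_scope: str = "same_strand",
) -> List[ReadthroughCall]:
    """Run the caller over every annotated feature (optionally one class).

    ``tracks`` holds one ProbeTrack per (chrom, strand) carrying both mutant
    and wildtype replicate samples.
    """
    calls: List[ReadthroughCall] = []
    for f in ann.features:
        if classes is not None and f.feature_class not in classes:
            continue
        track = tracks.get((f.chrom, f.strand))
        if track is None:
            raise KeyError(f"no probe track for ({f.chrom},{f.strand})")
        diffs = downstream_diffs(
            f,
            track,
            track,
            params,
            mut_samples=mut_samples,
            wt_samples=wt_samples,
            chrom_length=ann.chrom_lengths.get(f.chrom),
        )
        nd = downstream_neighbor_distance(f, ann, scope=neighbor_scope)
        calls.append(call_readthrough(f, diffs, nd, params))
    return calls


@dataclass
class ClassSummary:
    feature_class: str
    n_total_annotated: int
    n_excluded: int
    n_tested: int
    n_positive: int

    @property
    def fraction_positive(self) -> float:
        return self.n_positive / self.n_tested if self.n_tested else float("nan")


def summarize_by_class(calls: Sequence[ReadthroughCall]) -> List[ClassSummary]:
    """Per-class counts of tested/excluded/positive features.

    Fractions are kept unrounded; render as percentages only for display.
    """
    out: List[ClassSummary] = []
    for cls in sorted({c.feature_class for c in calls}):
        sub = [c for c in calls if c.feature_class == cls]
        n_exc = sum(c.excluded for c in sub)
        out.append(
            ClassSummary(
                feature_class=cls,
                n_total_annotated=len(sub),
                n_excluded=n_exc,
                n_tested=len(sub) - n_exc,
                n_positive=sum(c.call for c in sub),
            )
        )
    return out


def metagene_profile(
    features: Sequence[Feature],
    tracks: Dict[TrackKey, ProbeTrack],
    sample_ids: Sequence[str],
    upstream_bp: int,
    downstream_bp: int,
    bin_width: int = 25,
    chrom_lengths: Optional[Dict[str, int]] = None,
) -> pd.DataFrame:
    """Average 3'-aligned profile over many features.

    Per offset, the unweighted mean over features of each feature's bin mean;
    missing bins are omitted and the number of contributing features
    reported. Returns a DataFrame (offset_bin, offset_bp, mean, n_features).
    """
    if not features:
        raise ValueError("metagene requires at least one feature")
    n_up = upstream_bp // bin_width
    n_down = downstream_bp // bin_width
    offsets = np.arange(-n_up, n_down)
    sums = np.zeros(len(offsets))
    n_feat = np.zeros(len(offsets), dtype=np.int64)
    for f in features:
        track = tracks.get((f.chrom, f.strand))
        if track is None:
            raise KeyError(f"no probe track for ({f.chrom},{f.strand})")
        vals = average_replicates(track, list(sample_ids))
        prof = aligned_window(
            f,
            track,
            vals,
            upstream_bp,
            downstream_bp,
            bin_width,
            chrom_length=(chrom_lengths or {}).get(f.chrom),
        )
        ok = np.isfinite(prof.means)
        sums[ok] += prof.means[ok]
        n_feat[ok] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(n_feat > 0, sums / np.maximum(n_feat, 1), np.nan)
    return pd.DataFrame(
        {
            "offset_bin": offsets,
            "offset_bp": offsets * bin_width,
            "mean": mean,
            "n_features": n_feat,
        }
    )


def metagene_difference(
    features: Sequence[Feature],
    tracks: Dict[TrackKey, ProbeTrack],
    mut_samples: Sequence[str],
    wt_samples: Sequence[str],
    upstream_bp: int,
    downstream_bp: int,
    bin_width: int = 25,
    chrom_lengths: Optional[Dict[str, int]] = None,
) -> pd.DataFrame:
    """Mutant-minus-wildtype metagene (the inset view of the average profile)."""
    kw = dict(
        upstream_bp=upstream_bp,
        downstream_bp=downstream_bp,
        bin_width=bin_width,
        chrom_lengths=chrom_lengths,
    )
    mut = metagene_profile(features, tracks, mut_samples, **kw)
    wt = metagene_profile(features, tracks, wt_samples, **kw)
    out = mut[["offset_bin", "offset_bp"]].copy()
    out["diff"] = mut["mean"] - wt["mean"]
    out["n_features"] = np.minimum(mut["n_features"], wt["n_features"])
    return out


def calls_to_frame(calls: Sequence[ReadthroughCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        row = {"feature_id": c.feature_id, "feature_class": c.feature_class}
        row.update({f"diff_{i}": c.diffs[i] for i in range(len(c.diffs))})
        row.update(
            {
                "n_above": c.n_above,
                "excluded": c.excluded,
                "exclusion_reason": c.exclusion_reason,
                "call": c.call,
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)


def summaries_to_frame(summaries: Sequence[ClassSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "feature_class": s.feature_class,
                "n_total_annotated": s.n_total_annotated,
                "n_excluded": s.n_excluded,
                "n_tested": s.n_tested,
                "n_positive": s.n_positive,
                "fraction_positive": s.fraction_positive,
            }
            for s in summaries
        ]
    )


def positive_calls_bed(
    calls: Sequence[ReadthroughCall], ann: GenomeAnnotation
) -> pd.DataFrame:
    """BED6 rows for positive calls (the annotated feature intervals)."""
    rows = []
    for c in calls:
        if not c.call:
            continue
        f = ann[c.feature_id]
        rows.append(
            {
                "chrom": f.chrom,
                "start": f.start,
                "end": f.end,
                "name": f.id,
                "score": c.n_above,
                "strand": f.strand,
            }
        )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    )
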