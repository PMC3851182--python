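"""Genome annotation: transcription units, 3' ends and neighbor distances.

All coordinates are internally 0-based, half-open ``[start, end)``. BED input
is taken as-is; GFF3 (1-based, inclusive) is converted on read. The 3' end of
a feature is the anchor for every downstream-window computation in the
package: ``end`` on the + strand, ``start`` on the - strand.

Feature classes distinguish protein-coding ORFs from the short non-coding
transcript classes of the yeast genome (snoRNAs, CUTs, SUTs), which are
terminated by a different pathway and are the primary readthrough substrates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Iterator, List, Optional, Tuple

import gffutils.feature

FEATURE_CLASSES = ("ORF", "snoRNA", "CUT", "SUT", "other")

#: Prefix -> class map used when reading BED names (first match wins).
DEFAULT_CLASS_MAP: Dict[str, str] = {
    "snR": "snoRNA",
    "CUT": "CUT",
    "SUT": "SUT",
}
DEFAULT_CLASS = "ORF"


class AnnotationError(ValueError):
    """Malformed or inconsistent annotation input."""


@dataclass(frozen=True)
class Feature:
    """A single-interval transcription unit.

    ``start``/``end`` are 0-based half-open genomic coordinates; ``strand``
    is '+' or '-'.
    """

    id: str
    chrom: str
    start: int
    end: int
    strand: str
    feature_class: str = "other"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"feature {self.id!r}: require 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(
                f"feature {self.id!r}: strand must be '+' or '-', got {self.strand!r}"
            )
        if self.feature_class not in FEATURE_CLASSES:
            raise AnnotationError(
                f"feature {self.id!r}: unknown class {self.feature_class!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


def three_prime_end(f: Feature) -> int:
    """Anchor coordinate of the feature's 3' end.

    Returns ``end`` for + strand and ``start`` for - strand, i.e. the
    half-open boundary just past the last transcribed base, so the first
    downstream bin starts exactly here.
    """
    return f.end if f.strand == "+" else f.start


def five_prime_end(f: Feature) -> int:
    return f.start if f.strand == "+" else f.end


class GenomeAnnotation:
    """Ordered, validated collection of features with chromosome lengths.

    Features are queryable by (chrom, strand) in genomic position order.
    Chromosome lengths not supplied are inferred as the maximum feature end.
    """

    def __init__(
        self,
        features: Iterable[Feature],
        chrom_lengths: Optional[Dict[str, int]] = None,
    ) -> None:
        self.features: List[Feature] = list(features)
        seen = set()
        for f in self.features:
            if f.id in seen:
                raise AnnotationError(f"duplicate feature id {f.id!r}")
            seen.add(f.id)
        self.chrom_lengths: Dict[str, int] = dict(chrom_lengths or {})
        for f in self.features:
            self.chrom_lengths.setdefault(f.chrom, 0)
            if f.end > self.chrom_lengths[f.chrom]:
                if chrom_lengths is not None and f.chrom in chrom_lengths:
                    raise AnnotationError(
                        f"feature {f.id!r} extends past chromosome "
                        f"{f.chrom} length {chrom_lengths[f.chrom]}"
                    )
                self.chrom_lengths[f.chrom] = f.end
        self._by_id = {f.id: f for f in self.features}
        self._lanes: Dict[Tuple[str, str], List[Feature]] = {}
        for f in self.features:
            self._lanes.setdefault((f.chrom, f.strand), []).append(f)
        for lane in self._lanes.values():
            lane.sort(key=lambda f: (f.start, f.end, f.id))

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self) -> Iterator[Feature]:
        return iter(self.features)

    def __getitem__(self, feature_id: str) -> Feature:
        return self._by_id[feature_id]

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self._by_id

    def lane(self, chrom: str, strand: str) -> List[Feature]:
        """Features on one (chromosome, strand), sorted by start."""
        return self._lanes.get((chrom, strand), [])

    def by_class(self, feature_class: str) -> List[Feature]:
        return [f for f in self.features if f.feature_class == feature_class]


def downstream_neighbor_distance(
    f: Feature,
    ann: GenomeAnnotation,
    scope: str = "same_strand",
) -> Optional[int]:
    """Distance (bp) from f's 3' anchor to the nearest downstream transcript.

    "Downstream" is in f's direction of transcription. A neighbor beginning
    exactly at the anchor, or spanning it, gives distance 0. Returns None
    when no qualifying feature exists. ``scope`` is ``same_strand`` (default:
    the tiling data are strand-separated, so only same-strand neighbors
    collide with readthrough signal) or ``both_strands``.
    """
    hit = downstream_neighbor(f, ann, scope=scope)
    return None if hit is None else hit[1]


def downstream_neighbor(
    f: Feature,
    ann: GenomeAnnotation,
    scope: str = "same_strand",
) -> Optional[Tuple[Feature, int]]:
    """Nearest downstream transcript and its distance; None if there is none."""
    if scope not in ("same_strand", "both_strands"):
        raise ValueError(f"unknown neighbor scope {scope!r}")
    anchor = three_prime_end(f)
    strands = (f.strand,) if scope == "same_strand" else ("+", "-")
    best: Optional[Tuple[Feature, int]] = None
    for strand in strands:
        for g in ann.lane(f.chrom, strand):
            if g.id == f.id:
                continue
            if f.strand == "+":
                if g.start >= anchor:
                    d = g.start - anchor
                elif g.end > anchor:  # anchor lies inside g
                    d = 0
                else:
                    continue
            else:
                if g.end <= anchor:
                    d = anchor - g.end
                elif g.start < anchor:
                    d = 0
                else:
                    continue
            if best is None or d < best[1]:
                best = (g, d)
    return best


def _class_from_name(name: str, class_map: Dict[str, str], default: str) -> str:
    for prefix, cls in class_map.items():
        if name.startswith(prefix):
            return cls
    return default


def read_annotation(
    path: str,
    format: str = "BED",
    class_map: Optional[Dict[str, str]] = None,
    default_class: str = DEFAULT_CLASS,
    chrom_lengths: Optional[Dict[str, int]] = None,
) -> GenomeAnnotation:
    """Read a BED6 or GFF3 annotation into a validated GenomeAnnotation.

    BED is 0-based half-open; GFF3 is 1-based inclusive and converted. Class
    labels come from the GFF3 ``type`` (or a ``feature_class`` attribute)
    when it names a known class, otherwise from the name-prefix ``class_map``
    (default: snR* -> snoRNA, CUT* -> CUT, SUT* -> SUT, else ORF).
    """
    fmt = format.upper()
    if fmt not in ("BED", "GFF3"):
        raise ValueError(f"unknown annotation format {format!r}")
    cmap = DEFAULT_CLASS_MAP if class_map is None else class_map
    features: List[Feature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            try:
                if fmt == "BED":
                    features.append(_parse_bed_line(line, cmap, default_class))
                else:
                    feat = _parse_gff3_line(line, cmap, default_class)
                    if feat is not None:
                        features.append(feat)
            except AnnotationError as exc:
                raise AnnotationError(f"{path} line {lineno}: {exc}") from None
    return GenomeAnnotation(features, chrom_lengths=chrom_lengths)


def _parse_bed_line(line: str, cmap: Dict[str, str], default: str) -> Feature:
    fields = line.split("\t")
    if len(fields) < 6:
        raise AnnotationError(f"expected >=6 BED columns, got {len(fields)}")
    chrom, start_s, end_s, name, _score, strand = fields[:6]
    try:
        start, end = int(start_s), int(end_s)
    except ValueError:
        raise AnnotationError(f"non-integer coordinates {start_s!r}/{end_s!r}")
    if strand == ".":
        raise AnnotationError(f"feature {name!r}: strand is required, got '.'")
    return Feature(
        id=name, chrom=chrom, start=start, end=end, strand=strand,
        feature_class=_class_from_name(name, cmap, default),
    )


def _parse_gff3_line(
    line: str, cmap: Dict[str, str], default: str
) -> Optional[Feature]:
    try:
        g = gffutils.feature.feature_from_line(line)
    except Exception as exc:
        raise AnnotationError(f"unparseable GFF3 line: {exc}")
    if g.strand == "." or g.strand is None:
        raise AnnotationError("strand is required, got '.'")
    attrs = dict(g.attributes)
    fid = (attrs.get("ID") or attrs.get("Name") or [None])[0]
    if fid is None:
        raise AnnotationError("GFF3 feature has no ID or Name attribute")
    if g.featuretype in FEATURE_CLASSES:
        cls = g.featuretype
    elif "feature_class" in attrs and attrs["feature_class"][0] in FEATURE_CLASSES:
        cls = attrs["feature_class"][0]
    else:
        cls = _class_from_name(fid, cmap, default)
    # GFF3 1-based inclusive -> 0-based half-open
    return Feature(
        id=fid, chrom=g.seqid, start=g.start - 1, end=g.end,
        strand=g.strand, feature_class=cls,
    )


def write_annotation(ann: GenomeAnnotation, path: str) -> None:
    """Write the annotation as BED6 (score column 0)."""
    with open(path, "w") as fh:
        for f in ann.features:
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{f.id}\t0\t{f.strand}\n")


def neighbor_table(ann: GenomeAnnotation, scope: str = "same_strand"):
    """Per-feature (id, anchor, distance) rows, as a pandas DataFrame."""
    import pandas as pd

    rows = []
    for f in ann.features:
        hit = downstream_neighbor(f, ann, scope=scope)
        rows.append(
            {
                "feature_id": f.id,
                "feature_class": f.feature_class,
                "anchor": three_prime_end(f),
                "neighbor_id": None if hit is None else hit[0].id,
                "neighbor_distance": None if hit is None else hit[1],
            }
        )
    return pd.DataFrame(rows)
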