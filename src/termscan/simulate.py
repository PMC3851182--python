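"""Synthetic tiling and expression data with known ground truth.

The generator emulates the structure of a strand-specific yeast tiling-array
experiment: transcription units of several classes (ORF, snoRNA, CUT, SUT)
laid out without same-strand overlap, probes tiled every 8 bp on both
strands, expressed features raising log2 intensity above background, and —
for a planted subset of features — mutant-specific signal extending past the
3' end (readthrough) with an exponentially decaying profile. Probe-level
noise has two components: a per-probe affinity offset shared by every sample
(it cancels in mutant-minus-wildtype differences, as cross-hybridization
bias does on a real array) and i.i.d. Gaussian noise per probe per sample.

Expression matrices emulate the signature-comparison design: mutants measured
in replicate against a wildtype pool, with planted overlapping gene modules
(several mutants perturbing shared gene sets) so clustering and enrichment
have a known answer.

Everything is deterministic given (config, seed): a single
``numpy.random.default_rng(seed)`` stream consumed in a fixed order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .annotation import Feature, GenomeAnnotation, three_prime_end
from .signatures import ExpressionMatrix
from .tiling import ProbeTrack, TrackKey


def _default_class_counts() -> Dict[str, int]:
    return {"ORF": 60, "snoRNA": 24, "CUT": 12, "SUT": 12}


def _default_length_ranges() -> Dict[str, Tuple[int, int]]:
    return {
        "ORF": (600, 2000),
        "snoRNA": (80, 200),
        "CUT": (200, 600),
        "SUT": (200, 800),
    }


def _default_baselines() -> Dict[str, float]:
    # log2 units above background; short non-coding classes are weaker in wt
    return {"ORF": 3.0, "snoRNA": 4.0, "CUT": 1.0, "SUT": 2.0}


def _default_readthrough_fractions() -> Dict[str, float]:
    # planted readthrough rates per class; snoRNA and ORF rates follow the
    # reported genome-wide readthrough frequencies for a Ser2-kinase deletion
    return {"ORF": 0.028, "snoRNA": 32 / 77, "CUT": 0.3, "SUT": 0.3}


def _default_modules() -> List[Dict]:
    # overlapping mutant gene sets, one shared hub mutant, one
    # downregulated set
    return [
        {"name": "I", "members": ["ctk1", "sen1"], "size": 50, "effect": 3.0},
        {
            "name": "II",
            "members": ["ctk1", "set2", "rco1", "eaf3"],
            "size": 50,
            "effect": 3.0,
        },
        {
            "name": "III",
            "members": ["ctk1", "pcf11a", "pcf11b"],
            "size": 50,
            "effect": 3.0,
        },
        {"name": "IV", "members": ["ctk1", "rtt103"], "size": 50, "effect": -3.0},
    ]


@dataclass
class SimulationConfig:
    # genome / annotation
    n_chrom: int = 2
    chrom_length: int = 150_000
    class_counts: Dict[str, int] = field(default_factory=_default_class_counts)
    class_length_ranges: Dict[str, Tuple[int, int]] = field(
        default_factory=_default_length_ranges
    )
    gap_range: Tuple[int, int] = (300, 800)  # ordinary intergenic gaps, bp
    close_gap_range: Tuple[int, int] = (20, 149)  # gaps that trigger exclusion
    close_neighbor_fraction: Dict[str, float] = field(
        default_factory=lambda: {"ORF": 0.1, "snoRNA": 0.1, "CUT": 0.1, "SUT": 0.1}
    )
    start_margin: int = 1000
    end_margin: int = 2500
    # tiling signal
    probe_spacing: int = 8
    baseline_expression: Dict[str, float] = field(default_factory=_default_baselines)
    background_level: float = 0.0
    readthrough_fraction: Dict[str, float] = field(
        default_factory=_default_readthrough_fractions
    )
    readthrough_effect: float = 1.0  # Delta, log2 units at the 3' end
    readthrough_extent: int = 600  # bp of extended signal past the 3' end
    readthrough_decay: Optional[float] = 500.0  # exp decay length; None = flat
    noise_sd: float = 0.3  # per probe per sample, log2 units
    probe_affinity_sd: float = 0.25  # per probe, shared across samples
    n_replicates: int = 2  # tiling replicates per condition
    # expression matrix
    n_genes: int = 2000
    n_wt_samples: int = 20
    n_expr_replicates: int = 4
    expr_noise_sd: float = 0.2
    modules: List[Dict] = field(default_factory=_default_modules)

    def validate(self) -> List[str]:
        """All invariant violations at once (empty list = valid)."""
        errs = []
        if self.n_chrom < 1 or self.chrom_length < 1:
            errs.append("n_chrom and chrom_length must be positive")
        for cls, n in self.class_counts.items():
            if n < 0:
                errs.append(f"class count for {cls} is negative")
        for cls, fr in self.readthrough_fraction.items():
            if not (0 <= fr <= 1):
                errs.append(f"readthrough_fraction[{cls}] outside [0, 1]")
        for cls, fr in self.close_neighbor_fraction.items():
            if not (0 <= fr <= 1):
                errs.append(f"close_neighbor_fraction[{cls}] outside [0, 1]")
        if self.probe_spacing < 1:
            errs.append("probe_spacing must be >= 1")
        if self.noise_sd < 0 or self.probe_affinity_sd < 0 or self.expr_noise_sd < 0:
            errs.append("noise standard deviations must be >= 0")
        if self.readthrough_extent < 0:
            errs.append("readthrough_extent must be >= 0")
        if self.n_replicates < 1 or self.n_expr_replicates < 1:
            errs.append("replicate counts must be >= 1")
        if self.close_gap_range[1] >= 150 or self.close_gap_range[0] < 1:
            errs.append("close_gap_range must lie within [1, 149]")
        if self.gap_range[0] < 150:
            errs.append("gap_range minimum must be >= 150 (non-close neighbors)")
        return errs


_CLASS_PREFIX = {"ORF": "ORF", "snoRNA": "snR", "CUT": "CUT", "SUT": "SUT"}


def generate_annotation(
    cfg: SimulationConfig, seed: int
) -> Tuple[GenomeAnnotation, pd.DataFrame]:
    """Place non-overlapping same-strand features and plant ground truth.

    Returns the annotation and a truth table with one row per feature:
    close_neighbor (its downstream same-strand gap was drawn below 150 bp),
    readthrough_planted, delta and extent. Exactly
    ``round(fraction * count)`` features per class are made close neighbors
    (among those that have a downstream neighbor at all), and exactly
    ``round(fraction * count)`` get planted readthrough.
    """
    errs = cfg.validate()
    if errs:
        raise ValueError("; ".join(errs))
    rng = np.random.default_rng(seed)
    lanes = [
        (f"chr{i+1}", strand) for i in range(cfg.n_chrom) for strand in ("+", "-")
    ]
    # enumerate features with lengths, assign to lanes
    specs = []  # (class, length)
    counters: Dict[str, int] = {}
    for cls in sorted(cfg.class_counts):
        lo, hi = cfg.class_length_ranges[cls]
        for _ in range(cfg.class_counts[cls]):
            counters[cls] = counters.get(cls, 0) + 1
            fid = f"{_CLASS_PREFIX[cls]}{counters[cls]:04d}"
            specs.append((fid, cls, int(rng.integers(lo, hi + 1))))
    order = rng.permutation(len(specs))
    lane_members: Dict[TrackKey, List[Tuple[str, str, int]]] = {k: [] for k in lanes}
    for idx, lane_i in zip(order, rng.integers(0, len(lanes), size=len(specs))):
        lane_members[lanes[lane_i]].append(specs[idx])

    # choose close-neighbor features per class among those with a downstream
    # neighbor on their lane (+: not last; -: not first)
    eligible: Dict[str, List[str]] = {cls: [] for cls in cfg.class_counts}
    for (chrom, strand), members in lane_members.items():
        for i, (fid, cls, _ln) in enumerate(members):
            has_downstream = i < len(members) - 1 if strand == "+" else i > 0
            if has_downstream:
                eligible[cls].append(fid)
    close_ids = set()
    for cls in sorted(cfg.class_counts):
        frac = cfg.close_neighbor_fraction.get(cls, 0.0)
        n_close = int(round(frac * cfg.class_counts[cls]))
        pool = sorted(eligible[cls])
        if n_close > len(pool):
            raise ValueError(
                f"cannot place {n_close} close neighbors for class {cls}: "
                f"only {len(pool)} features have a downstream neighbor"
            )
        if n_close:
            close_ids |= set(rng.choice(pool, size=n_close, replace=False))

    features: List[Feature] = []
    for (chrom, strand), members in lane_members.items():
        pos = cfg.start_margin
        for i, (fid, cls, ln) in enumerate(members):
            features.append(
                Feature(
                    id=fid, chrom=chrom, start=pos, end=pos + ln,
                    strand=strand, feature_class=cls,
                )
            )
            if i == len(members) - 1:
                pos += ln
                continue
            # the gap after member i controls the neighbor distance of
            # member i on '+' lanes and of member i+1 on '-' lanes
            controller = fid if strand == "+" else members[i + 1][0]
            lo, hi = (
                cfg.close_gap_range if controller in close_ids else cfg.gap_range
            )
            pos += ln + int(rng.integers(lo, hi + 1))
        if pos > cfg.chrom_length - cfg.end_margin:
            raise ValueError(
                f"genome too small: lane ({chrom},{strand}) needs {pos} bp "
                f"+ {cfg.end_margin} bp margin of {cfg.chrom_length}"
            )

    # plant readthrough per class
    rt_ids = set()
    by_class: Dict[str, List[str]] = {}
    for f in features:
        by_class.setdefault(f.feature_class, []).append(f.id)
    for cls in sorted(cfg.class_counts):
        frac = cfg.readthrough_fraction.get(cls, 0.0)
        ids = sorted(by_class.get(cls, []))
        n_rt = int(round(frac * len(ids)))
        if n_rt:
            rt_ids |= set(rng.choice(ids, size=n_rt, replace=False))

    features.sort(key=lambda f: (f.chrom, f.start, f.strand, f.id))
    ann = GenomeAnnotation(
        features, chrom_lengths={c: cfg.chrom_length for c, _s in lanes}
    )
    truth = pd.DataFrame(
        [
            {
                "feature_id": f.id,
                "feature_class": f.feature_class,
                "chrom": f.chrom,
                "strand": f.strand,
                "start": f.start,
                "end": f.end,
                "close_neighbor": f.id in close_ids,
                "readthrough_planted": f.id in rt_ids,
                "delta": cfg.readthrough_effect if f.id in rt_ids else 0.0,
                "extent": cfg.readthrough_extent if f.id in rt_ids else 0,
            }
            for f in ann.features
        ]
    )
    return ann, truth


def _expected_signal(
    ann: GenomeAnnotation,
    truth: pd.DataFrame,
    cfg: SimulationConfig,
    chrom: str,
    strand: str,
    positions: np.ndarray,
    mutant: bool,
) -> np.ndarray:
    sig = np.full(len(positions), cfg.background_level, dtype=float)
    planted = set(truth.loc[truth["readthrough_planted"], "feature_id"])
    for f in ann.lane(chrom, strand):
        base = cfg.baseline_expression.get(f.feature_class, 0.0)
        sig[(positions >= f.start) & (positions < f.end)] += base
        if mutant and f.id in planted and cfg.readthrough_extent > 0:
            anchor = three_prime_end(f)
            if strand == "+":
                d = positions - anchor
            else:
                d = anchor - 1 - positions
            inside = (d >= 0) & (d < cfg.readthrough_extent)
            if cfg.readthrough_decay is None:
                tail = cfg.readthrough_effect * np.ones(inside.sum())
            else:
                tail = cfg.readthrough_effect * np.exp(
                    -d[inside] / cfg.readthrough_decay
                )
            sig[inside] += tail
    return sig


def generate_tracks(
    ann: GenomeAnnotation,
    truth: pd.DataFrame,
    cfg: SimulationConfig,
    seed: int,
) -> Dict[TrackKey, ProbeTrack]:
    """Simulate wt and mutant replicate probe tracks over the annotation.

    Probes sit every ``probe_spacing`` bp on both strands. Samples are named
    ``wt_1..wt_n`` and ``mut_1..mut_n``. The per-probe affinity offset is
    drawn once per (chrom, strand) probe and added to every sample.
    """
    rng = np.random.default_rng(seed)
    wt_ids = [f"wt_{i+1}" for i in range(cfg.n_replicates)]
    mut_ids = [f"mut_{i+1}" for i in range(cfg.n_replicates)]
    tracks: Dict[TrackKey, ProbeTrack] = {}
    for chrom in sorted(ann.chrom_lengths):
        length = ann.chrom_lengths[chrom]
        for strand in ("+", "-"):
            positions = np.arange(0, length, cfg.probe_spacing, dtype=np.int64)
            affinity = rng.normal(0.0, cfg.probe_affinity_sd, len(positions))
            wt_mu = _expected_signal(ann, truth, cfg, chrom, strand, positions, False)
            mut_mu = _expected_signal(ann, truth, cfg, chrom, strand, positions, True)
            samples: Dict[str, np.ndarray] = {}
            for sid in wt_ids:
                samples[sid] = wt_mu + affinity + rng.normal(
                    0.0, cfg.noise_sd, len(positions)
                )
            for sid in mut_ids:
                samples[sid] = mut_mu + affinity + rng.normal(
                    0.0, cfg.noise_sd, len(positions)
                )
            tracks[(chrom, strand)] = ProbeTrack(
                chrom=chrom, strand=strand, positions=positions, samples=samples
            )
    return tracks


def generate_expression_matrix(
    cfg: SimulationConfig, seed: int
) -> Tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate a gene x sample log2-ratio matrix with planted modules.

    Genes are assigned to disjoint module blocks from the front of the gene
    list; each mutant shifts its module genes by the module effect. Wildtype
    pool samples are noise only. Returns (matrix, truth) where truth has one
    row per (gene, module) membership with the planted effect.
    """
    errs = cfg.validate()
    if errs:
        raise ValueError("; ".join(errs))
    rng = np.random.default_rng(seed)
    genes = [f"G{i+1:05d}" for i in range(cfg.n_genes)]
    mutants: List[str] = []
    for mod in cfg.modules:
        for m in mod["members"]:
            if m not in mutants:
                mutants.append(m)
    needed = sum(m["size"] for m in cfg.modules)
    if needed > cfg.n_genes:
        raise ValueError(f"{needed} module genes requested but only {cfg.n_genes}")
    # disjoint gene blocks per module, from the front of the list
    truth_rows = []
    effect = pd.DataFrame(0.0, index=genes, columns=mutants)
    cursor = 0
    for mod in cfg.modules:
        block = genes[cursor : cursor + mod["size"]]
        cursor += mod["size"]
        for g in block:
            truth_rows.append(
                {"gene": g, "module": mod["name"], "effect": mod["effect"]}
            )
            for m in mod["members"]:
                effect.loc[g, m] += mod["effect"]
    columns: Dict[str, np.ndarray] = {}
    groups = {}
    for i in range(cfg.n_wt_samples):
        sid = f"wt_{i+1}"
        columns[sid] = rng.normal(0.0, cfg.expr_noise_sd, cfg.n_genes)
        groups[sid] = "wt"
    for m in mutants:
        mu = effect[m].to_numpy()
        for r in range(cfg.n_expr_replicates):
            sid = f"{m}_{r+1}"
            columns[sid] = mu + rng.normal(0.0, cfg.expr_noise_sd, cfg.n_genes)
            groups[sid] = m
    mat = ExpressionMatrix(
        values=pd.DataFrame(columns, index=pd.Index(genes, name="gene")),
        groups=pd.Series(groups, name="group"),
    )
    return mat, pd.DataFrame(truth_rows)


def config_from_dict(d: Dict) -> SimulationConfig:
    """Build a SimulationConfig from a (YAML-loaded) plain dict."""
    known = {f for f in SimulationConfig.__dataclass_fields__}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
    d = dict(d)
    for key in ("gap_range", "close_gap_range"):
        if key in d:
            d[key] = tuple(d[key])
    if "class_length_ranges" in d:
        d["class_length_ranges"] = {
            k: tuple(v) for k, v in d["class_length_ranges"].items()
        }
    return SimulationConfig(**d)
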