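import numpy as np
import pytest

from termscan.annotation import Feature, GenomeAnnotation
from termscan.tiling import ProbeTrack


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_track(positions, strand="+", chrom="chrI", **samples):
    positions = np.asarray(positions, dtype=np.int64)
    return ProbeTrack(
        chrom=chrom,
        strand=strand,
        positions=positions,
        samples={k: np.asarray(v, dtype=float) for k, v in samples.items()},
    )


def random_annotation(rng, n_features, chrom_length=10_000, n_chrom=2):
    """Random possibly-overlapping features for brute-force oracle tests."""
    feats = []
    for i in range(n_features):
        chrom = f"chr{rng.integers(1, n_chrom + 1)}"
        start = int(rng.integers(0, chrom_length - 200))
        length = int(rng.integers(50, 400))
        feats.append(
            Feature(
                id=f"f{i}",
                chrom=chrom,
                start=start,
                end=min(start + length, chrom_length),
                strand="+" if rng.random() < 0.5 else "-",
                feature_class="other",
            )
        )
    return GenomeAnnotation(feats, chrom_lengths={f"chr{c+1}": chrom_length for c in range(n_chrom)})
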