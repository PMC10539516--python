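import numpy as np
import pytest

from sdscan.genotypes import GenotypeMatrix, Marker, SampleMeta


def build_matrix(
    genotypes,
    sexes=None,
    roles=None,
    depth=None,
    replicate_groups=None,
    radtags=None,
    monomorphic=None,
):
    """Construct a GenotypeMatrix from a plain nested list of codes."""
    g = np.asarray(genotypes, dtype=np.int8)
    n_mark, n_samp = g.shape
    sexes = list(sexes) if sexes is not None else ["unknown"] * n_samp
    roles = list(roles) if roles is not None else ["adult"] * n_samp
    replicate_groups = list(replicate_groups) if replicate_groups is not None else [None] * n_samp
    radtags = list(radtags) if radtags is not None else [f"tag{i // 2:04d}" for i in range(n_mark)]
    monomorphic = list(monomorphic) if monomorphic is not None else [False] * n_mark
    markers = [
        Marker(
            marker_id=f"m{i:04d}",
            radtag_id=radtags[i],
            snp_offset=i % 2,
            alt_allele=None if monomorphic[i] else "C",
        )
        for i in range(n_mark)
    ]
    samples = [
        SampleMeta(f"s{j:03d}", role=roles[j], sex=sexes[j], replicate_group=replicate_groups[j])
        for j in range(n_samp)
    ]
    return GenotypeMatrix(
        markers=markers,
        samples=samples,
        genotypes=g,
        depth=None if depth is None else np.asarray(depth, dtype=np.int32),
    )


@pytest.fixture
def matrix_factory():
    return build_matrix


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
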