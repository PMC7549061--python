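import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import musaqc as mq

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_pair() -> mq.SubgenomePair:
    """Two 20 kb chromosomes, ~100 divergent sites, a few B-private indels."""
    return mq.generate_subgenomes(
        seed=11, n_chrom=2, chrom_length=20_000, divergence_rate=0.005, indel_rate=2e-4
    )


@pytest.fixture(scope="session")
def bb_pileup(small_pair) -> list[mq.PileupColumn]:
    acc = mq.compose_genotype(small_pair, mq.GenotypeSpec("BB"))
    return mq.simulate_pileup(acc, mean_depth=30, error_rate=0.005, seed=21)


@pytest.fixture(scope="session")
def diagnostic_snps(small_pair, bb_pileup) -> list[mq.DiagnosticSNP]:
    calls = mq.call_variants(bb_pileup, error_rate=0.005)
    filtered = mq.filter_variants(calls, mq.FilterConfig())
    return mq.identify_informative_snps(filtered, bb_pileup, hom_fraction=0.9)


def random_calls(rng: np.random.Generator, n: int, chrom: str = "chr01") -> list[mq.VariantCall]:
    """Coordinate-sorted random call sets mixing SNPs and indels."""
    positions = np.sort(rng.choice(np.arange(1, 50_000), size=n, replace=False))
    calls = []
    for pos in positions:
        ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
        is_indel = rng.random() < 0.3
        calls.append(
            mq.VariantCall(
                chrom=chrom,
                pos=int(pos),
                ref_allele=ref,
                alt_alleles=(ref + "N",) if is_indel else (alt,),
                qual=float(np.round(rng.uniform(0, 80), 3)),
                dp=int(rng.integers(1, 60)),
                idv=int(rng.integers(0, 8)) if is_indel else 0,
                is_indel=bool(is_indel),
            )
        )
    return calls
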