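import numpy as np
import pytest

from mitocompare.mitio import GeneFeature, MitogenomeRecord
from mitocompare.simulate import CladeSpec, RepeatPlan, simulate_clade


@pytest.fixture(scope="session")
def small_clade():
    """Five-species clade with planted introns and repeats, shared by many
    tests (session-scoped: generation is deterministic)."""
    spec = CladeSpec(
        n_species=5, seed=7,
        intron_plan={383: {"sp01", "sp02", "sp03"}, 706: {"sp01"}},
        repeat_plan=[
            RepeatPlan(species="sp01", kind="direct", length=246),
            RepeatPlan(species="sp01", kind="tandem", length=120, period=5),
            RepeatPlan(species="sp02", kind="inverted", length=100),
        ],
    )
    records, truth = simulate_clade(spec)
    return spec, records, truth


@pytest.fixture(scope="session")
def rearranged_clade():
    """Four species, two of which carry gene-order operations."""
    spec = CladeSpec(
        n_species=4, seed=11, branch_length=0.03,
        gene_order_ops={"sp02": {"inversions": 1},
                        "sp04": {"inversions": 1, "transpositions": 1}},
    )
    records, truth = simulate_clade(spec)
    return spec, records, truth


@pytest.fixture
def toy_record():
    """1 kb linear genome with one 300 bp CDS (hand-built ground truth)."""
    rng = np.random.default_rng(0)
    seq = "".join(rng.choice(list("ACGT"), size=1000))
    seq = seq[:100] + "ATG" + seq[103:397] + "TAA" + seq[400:]
    feat = GeneFeature(name="cox1", category="core_pcg", strand="+",
                       spans=[(100, 400)])
    return MitogenomeRecord(id="toy", sequence=seq, topology="linear",
                            features=[feat])
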