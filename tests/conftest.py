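import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from cleavemap.reference import AnticodonSpec, Feature, GenomeBundle
from cleavemap.simulate import SimConfig, default_cleavage_implants, generate_reference


@pytest.fixture(scope="session")
def toy_genome() -> GenomeBundle:
    """Hand-built genome: two identical gln tRNAs (+), one lys tRNA (-),
    two CDSs, on one 900-nt reference."""
    rng = np.random.default_rng(1234)
    seq = rng.choice(list("ACGT"), size=900)

    def trna_body(anticodon, rng):
        body = rng.choice(list("ACGT"), size=76)
        body[34:37] = list(anticodon)
        return "".join(body)

    gln_body = trna_body("TTG", rng)
    lys_body = trna_body("TTT", rng)

    from cleavemap.reference import reverse_complement

    seq[50:126] = list(gln_body)
    seq[200:276] = list(gln_body)
    seq[350:426] = list(reverse_complement(lys_body))

    features = [
        Feature("glnU", "chr", 50, 126, "+", "tRNA"),
        Feature("glnW", "chr", 200, 276, "+", "tRNA"),
        Feature("lysT", "chr", 350, 426, "-", "tRNA"),
        Feature("orfA", "chr", 500, 650, "+", "CDS"),
        Feature("orfB", "chr", 700, 820, "-", "CDS"),
    ]
    bundle = GenomeBundle(
        sequences={"chr": "".join(seq)},
        features=features,
        trna_index={
            "glnU": AnticodonSpec("TTG", 34),
            "glnW": AnticodonSpec("TTG", 34),
            "lysT": AnticodonSpec("TTT", 34),
        },
    )
    bundle.validate()
    return bundle


@pytest.fixture(scope="session")
def sim_bundle():
    """One default synthetic genome + config with 20 N1 implants."""
    cfg = SimConfig(seed=7, n1_fraction=1.0)
    bundle = generate_reference(cfg)
    cfg.implanted_cleavage = default_cleavage_implants(bundle, cfg, n=20, effect=6.0)
    return cfg, bundle
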