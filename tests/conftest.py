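import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from xlms import synthetic_data as sd
from xlms.xl_tables import CsmRecord

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def random_records(rng: np.random.Generator, n: int, n_proteins: int = 8, max_site: int = 60):
    """Random CSM records over a small protein universe (shared test helper)."""
    proteins = [f"P{i:02d}" for i in range(1, n_proteins + 1)]
    out = []
    for k in range(n):
        out.append(
            CsmRecord(
                protein_a=proteins[rng.integers(n_proteins)],
                site_a=int(rng.integers(1, max_site + 1)),
                protein_b=proteins[rng.integers(n_proteins)],
                site_b=int(rng.integers(1, max_site + 1)),
                score=float(rng.uniform(0, 80)),
                fdr_level=float(rng.uniform(0, 0.1)),
                condition=("DR", "IT")[rng.integers(2)],
                replicate=int(rng.integers(1, 4)),
                peptide_pair_id=f"pp{k}",
            )
        )
    return out


@pytest.fixture(scope="session")
def helix_monomer():
    model, seq = sd.gen_structure(60, "helix", lys_fraction=0.25, seed=3)
    return model, seq


@pytest.fixture(scope="session")
def c2_dimer(helix_monomer):
    model, _ = helix_monomer
    assembly, truth = sd.gen_assembly(model, n_copies=2, symmetry="C2", contact=5.0, seed=6)
    return assembly, truth
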