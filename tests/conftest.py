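import numpy as np
import pytest

from wgpmap import simgen
from wgpmap.assembly import AssemblyParams, Fingerprint
from wgpmap.config import RunConfig
from wgpmap import pipeline


@pytest.fixture(scope="session")
def small_params():
    return AssemblyParams(gel_length_G=3000, cb_unit=6311, final_cutoff_exponent=-10)


@pytest.fixture(scope="session")
def tiled_fingerprints():
    """Noise-free fingerprints from a 5 Mb arm at 8x coverage (ground-truthed)."""
    model = simgen.simulate_chromosome(5_000_000, 2_000_000, 50, seed=2)
    clones = simgen.simulate_bac_library(model, 8.0, purity=1.0, seed=2)
    fpd, origin, pos = simgen.simulate_wgp_tags(model, clones, dropout=0.0, seed=2)
    fps = [Fingerprint(b, t) for b, t in sorted(fpd.items()) if t]
    return model, clones, fps, origin, pos


@pytest.fixture(scope="session")
def pipeline_run():
    """One moderate-scale end-to-end run shared by the recovery checks."""
    cfg = RunConfig(
        seed=3,
        simulate=dict(
            length=40_000_000,
            arm_boundary=18_000_000,
            n_genes=400,
            coverage=9.0,
            purity=0.85,
            n_markers=200,
            n_rh_lines=355,
        ),
        # stop merging early: a deliberately fragmented map gives many small
        # contigs, a harder and better-powered placement experiment
        assemble=dict(final_cutoff_exponent=-40),
    )
    return pipeline.run(cfg, upto="compare")
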