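import numpy as np
import pytest

from itss.tracks_io import CoverageTrack, GenomeLayout


@pytest.fixture
def layout():
    return GenomeLayout({"chrI": 2000, "chrII": 1500})


@pytest.fixture
def make_track(layout):
    def _make(values=None, label="t", fill=0.0):
        vals = {
            s: np.full(n, float(fill)) for s, n in layout.lengths.items()
        }
        if values:
            for seq, arr in values.items():
                vals[seq][: len(arr)] = arr
        return CoverageTrack(layout=layout, values=vals, label=label)

    return _make


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete simulation shared by integration-style tests."""
    from itss.synthetic_data import SimSpec, simulate

    spec = SimSpec(
        seed=7,
        chrom_lengths=(120_000,),
        n_genes=20,
        n_internal=4,
        n_tes_decoys=2,
    )
    return simulate(spec)


@pytest.fixture(scope="session")
def small_run(small_sim):
    from itss.motif_enrichment import load_pwm
    from itss.cli import default_pwm_path
    from itss.pipeline import run_all

    mse = load_pwm(default_pwm_path("mse"))
    urs1 = load_pwm(default_pwm_path("urs1"))
    scan, called, motifs = run_all(
        small_sim.control,
        small_sim.tests,
        small_sim.annotation,
        small_sim.genome,
        small_sim.exclusions,
        mse,
        urs1,
    )
    return scan, called, motifs
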