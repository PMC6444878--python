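import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from nucshift.io_formats import Fragment, FragmentSet
from nucshift.synthetic import ShiftProgram, program_shifts, sample_fragments, simulate_genome


@pytest.fixture(scope="session")
def small_model():
    """12-gene genome with programmed +1 shifts in every bin/direction combo."""
    model = simulate_genome(
        n_genes=12, chrom_len=80_000, spacing=190, ndr_width=150,
        n_nucs_per_side=3, seed=11, ndr_offset=100,
    )
    gids = [g.gene_id for g in model.genes]
    programs = [
        ShiftProgram(1, "downstream", 30, (gids[0],)),
        ShiftProgram(1, "upstream", 30, (gids[1],)),
        ShiftProgram(1, "downstream", 75, (gids[2],)),
        ShiftProgram(1, "upstream", 75, (gids[3],)),
        ShiftProgram(1, "downstream", 125, (gids[4],)),
        ShiftProgram(1, "upstream", 125, (gids[5],)),
        ShiftProgram(1, "downstream", 175, (gids[6],)),
        ShiftProgram(1, "upstream", 175, (gids[7],)),
    ]
    return program_shifts(model, programs)


@pytest.fixture(scope="session")
def clean_fragments(small_model):
    """Noise-free fragments: every dyad exactly on its truth position."""
    a = sample_fragments(small_model, "control", depth_per_nuc=20,
                         len_mean=147, len_sd=0, dyad_jitter_sd=0, seed=21)
    b = sample_fragments(small_model, "treatment", depth_per_nuc=20,
                         len_mean=147, len_sd=0, dyad_jitter_sd=0, seed=22)
    return a, b


@pytest.fixture
def tiny_frags():
    frags = [
        Fragment("chr1", 100, 247),
        Fragment("chr1", 100, 247),
        Fragment("chr1", 300, 450),
        Fragment("chr2", 50, 190),
    ]
    return FragmentSet("tiny", frags, 4)
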