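import numpy as np
import pandas as pd
import pytest

from intronsens import SimConfig
from intronsens.junctions import IntronAnnotation


@pytest.fixture
def toy_event():
    """Single intron [100, 400) on chr1 between exons [0,100) and [400,500)."""
    return IntronAnnotation(
        gene_id="TOY1",
        chrom="chr1",
        strand="+",
        exons=[(0, 100), (400, 500)],
        intron_index=0,
    )


@pytest.fixture
def small_counts():
    """Hand-built junction-count table: 3 events x 2 doses x 2 replicates."""
    rows = []
    spec = {
        # event: {dose: [(N_EE, N_IE) per replicate]}
        "evA": {0.0: [(80, 20), (90, 10)], 0.5: [(40, 60), (50, 50)]},
        "evB": {0.0: [(60, 60), (40, 40)], 0.5: [(30, 70), (20, 80)]},
        "evC": {0.0: [(50, 49), (50, 49)], 0.5: [(10, 80), (20, 70)]},  # mean 99
    }
    for ev, per_dose in spec.items():
        for dose, reps in per_dose.items():
            for r, (ee, ie) in enumerate(reps, start=1):
                rows.append(
                    {
                        "event_id": ev,
                        "strain": "hsh155-ds",
                        "treatment": "DMSO" if dose == 0 else "Plad-B",
                        "dose_uM": dose,
                        "replicate": r,
                        "N_EE": ee,
                        "N_IE": ie,
                    }
                )
    return pd.DataFrame(rows)


@pytest.fixture
def smit_panel_config():
    """Designed SMIT panel, one uninhibited condition, modest depth."""
    from intronsens.synthio import designed_smit_panel

    return designed_smit_panel(seed=0, reads_per_gene=5000,
                               smit_conditions={"control": 1.0})
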