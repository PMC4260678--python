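"""Shared fixtures: diagnostic-SNP panel and a simulated two-timepoint scenario."""

from __future__ import annotations

import numpy as np
import pytest

import wolbtrack as w
from wolbtrack.clades import CladeSNPTable
from wolbtrack.scenarios import BP_RELATIVE, CLADES, cold_regime_params, diagnostic_panel

# re-exported for test modules
make_snp_table = diagnostic_panel
cold_params = cold_regime_params


@pytest.fixture(scope="session")
def snp_table() -> CladeSNPTable:
    return diagnostic_panel()


@pytest.fixture(scope="session")
def pipeline_dir(tmp_path_factory):
    """On-disk two-timepoint fixture: sync files for generation 0 and 15
    (three replicates, clade V under s=0.18), clade table, pipeline config."""
    import yaml

    from wolbtrack.sync_io import write_clade_table, write_sync

    root = tmp_path_factory.mktemp("pipeline")
    table = diagnostic_panel()
    trajs = w.simulate_trajectory(cold_regime_params(seed=42))
    rng = np.random.default_rng(4242)
    start_pools = [t[0].wolbachia_clade_frequencies() for t in trajs]
    end_pools = [t[-1].wolbachia_clade_frequencies() for t in trajs]
    write_sync(w.sample_poolseq_counts(start_pools, table, 80, 0.001, rng), root / "start.sync")
    write_sync(w.sample_poolseq_counts(end_pools, table, 80, 0.001, rng), root / "end.sync")
    write_clade_table(table.to_frame(), root / "clades.tsv")
    config = {
        "sync_start": str(root / "start.sync"),
        "sync_end": str(root / "end.sync"),
        "clade_table": str(root / "clades.tsv"),
        "output_dir": str(root / "out"),
        "focal_clade": "V",
        "target_coverage": 50,
        "effective_size": 75,
        "generations": 15,
        "seed": 7,
    }
    with open(root / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh)
    return root
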