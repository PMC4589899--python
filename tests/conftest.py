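import numpy as np
import pandas as pd
import pytest

from txdesign import (
    HaplotypePanel,
    MarkerManifest,
    SimulationSpec,
    simulate_panel,
)


@pytest.fixture(scope="session")
def two_pop_panel() -> HaplotypePanel:
    """Moderate two-population panel with block LD and drift."""
    spec = SimulationSpec(
        populations=[("CEU", 60), ("AFR", 60)],
        n_blocks=12,
        markers_per_block=6,
        within_block_correlation=0.9,
        fst=0.1,
        seed=11,
    )
    return simulate_panel(spec)


@pytest.fixture(scope="session")
def perfect_block_panel() -> HaplotypePanel:
    """Panel with perfect founder copying: intra-block r² is exactly 1."""
    spec = SimulationSpec(
        populations=[("CEU", 40)],
        n_blocks=4,
        markers_per_block=5,
        within_block_correlation=1.0,
        fst=0.0,
        seed=5,
    )
    return simulate_panel(spec)


def toy_manifest(n: int, chrom: str = "1", spacing: int = 1000, prefix: str = "m") -> MarkerManifest:
    """Hand-sized manifest with evenly spaced markers."""
    return MarkerManifest(
        pd.DataFrame(
            {
                "marker_id": [f"{prefix}{i}" for i in range(n)],
                "chrom": chrom,
                "pos": 1 + spacing * np.arange(n),
                "ref": "A",
                "alt": "G",
                "modules": [set() for _ in range(n)],
            }
        )
    )


def panel_from_haplotypes(haps: np.ndarray, populations: dict[str, str] | None = None,
                          manifest: MarkerManifest | None = None) -> HaplotypePanel:
    """Wrap an explicit (markers x haplotypes) 0/1 matrix as a panel."""
    haps = np.asarray(haps, dtype=np.int8)
    n_samples = haps.shape[1] // 2
    samples = [f"s{i}" for i in range(n_samples)]
    if populations is None:
        populations = {s: "POP" for s in samples}
    if manifest is None:
        manifest = toy_manifest(haps.shape[0])
    return HaplotypePanel(haps, samples, populations, manifest)
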