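import numpy as np
import pytest

from supercellgraph import CellTable, PipelineConfig, SyntheticSpec, generate_dataset


@pytest.fixture(scope="session")
def small_spec() -> SyntheticSpec:
    """3 classes x 5 images, defaults otherwise: enough for cohort-level fits."""
    return SyntheticSpec(n_images_per_class=5, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    tables, labels, truths = generate_dataset(small_spec)
    return tables, labels, truths


@pytest.fixture()
def config() -> PipelineConfig:
    return PipelineConfig(random_seed=7)


@pytest.fixture()
def line_table() -> CellTable:
    """Three cells on a line at x = 0, 1, 10: the canonical local-graph example."""
    return CellTable(
        image_id="line",
        cell_ids=[1, 2, 3],
        xy=[(0.0, 0.0), (1.0, 0.0), (10.0, 0.0)],
        features=np.zeros((3, 1)),
        feature_names=["f0"],
    )


def random_table(rng: np.random.Generator, n: int, extent: float = 100.0, F: int = 2,
                 image_id: str = "rand") -> CellTable:
    return CellTable(
        image_id=image_id,
        cell_ids=np.arange(n),
        xy=rng.uniform(0, extent, size=(n, 2)),
        features=rng.normal(size=(n, F)),
        feature_names=[f"f{j}" for j in range(F)],
    )
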