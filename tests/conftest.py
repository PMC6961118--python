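import numpy as np
import pandas as pd
import pytest

import thetascreen as ts


@pytest.fixture(scope="session")
def small_config():
    return ts.ScreenSimConfig(
        n_cell_lines=2,
        n_compounds=40,
        n_replicates=2,
        plate_format=96,
        n_features=60,
        n_fields_per_well=2,
        cells_per_image_range=(5, 8),
        frac_inactive=0.3,
        effect_magnitude_range=(3.0, 6.0),
        plate_effect_sd=0.2,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_screen(small_config):
    """A 2-line x 40-compound screen shared (read-only) across tests."""
    cells, layout, gt = ts.generate_screen(small_config)
    return cells, layout, gt


@pytest.fixture(scope="session")
def small_pipeline(small_screen):
    """The small screen taken through ingest -> normalized profiles -> PC space."""
    cells, layout, gt = small_screen
    cells, _ = ts.qc_filter_images(cells, ts.QCThresholds(sat_max=0.2, focus_min=10.0))
    wells = ts.join_layout(
        ts.aggregate_to_well(ts.aggregate_to_image_median(cells)), layout
    )
    selected, _ = ts.select_features(wells)
    normed = ts.normalize_to_dmso(selected)
    model = ts.fit_pca(normed, variance_prop=0.9)
    centered = ts.project_and_center(model, normed)
    return {"wells": wells, "normed": normed, "model": model, "centered": centered,
            "layout": layout, "gt": gt}


@pytest.fixture()
def toy_cells():
    """Tiny hand-written per-cell table: 1 plate, 2 wells, 2 features."""
    return pd.DataFrame(
        {
            "plate": ["P1"] * 6,
            "well": ["A01"] * 3 + ["A02"] * 3,
            "image_id": [1, 1, 1, 1, 1, 1],
            "object_id": [1, 2, 3, 1, 2, 3],
            "qc_saturation": [0.01] * 6,
            "qc_focus": [100.0] * 6,
            "f1": [1.0, 2.0, 9.0, 4.0, 5.0, 6.0],
            "f2": [0.5, 0.6, 0.7, 1.5, 1.6, 1.7],
        }
    )


def make_centered_table(coords: np.ndarray, compounds, cell_line="CL01", replicate=1,
                        roles=None) -> ts.CenteredPCTable:
    """Wrap raw coordinates as a CenteredPCTable for direct scoring tests."""
    k = coords.shape[1]
    df = pd.DataFrame(coords, columns=[f"pc_{i + 1}" for i in range(k)])
    df.insert(0, "compound", list(compounds))
    df.insert(1, "cell_line", cell_line)
    df.insert(2, "replicate", replicate)
    df.insert(3, "role", roles if roles is not None else "treatment")
    return ts.CenteredPCTable(data=df, offset=np.zeros(k), k=k)
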