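import numpy as np
import pandas as pd
import pytest

from ctdensity.io import Deployment, SequenceRecord


@pytest.fixture
def deployments_small():
    """Five cameras on a 2-km lattice, one 50-day winter window."""
    start = pd.Timestamp("2021-01-01")
    return [
        Deployment(
            camera_id=f"cam{k}",
            x_km=float(k % 3) * 2.0,
            y_km=float(k // 3) * 2.0,
            start=start,
            end=start + pd.Timedelta(days=50),
            year_index=1,
        )
        for k in range(5)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_sequence(
    camera="cam0",
    species="boar",
    when="2021-01-05 12:00",
    n=1,
    radius=4.0,
    angle=0.1,
    path=6.0,
    duration=10.0,
    behaviour="walk",
):
    return SequenceRecord(
        species=species,
        camera_id=camera,
        start_time=pd.Timestamp(when),
        n_individuals=n,
        entry_radius_m=radius,
        entry_angle_rad=angle,
        path_length_m=path,
        duration_s=duration,
        behaviour=behaviour,
    )
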