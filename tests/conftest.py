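import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def make_daily():
    """Factory for a single-depth daily-mean temperature series."""

    def _make(temps, start="2000-01-01", depth_m=4.0):
        temps = np.asarray(temps, dtype=float)
        dates = pd.date_range(start, periods=len(temps), freq="D")
        return pd.DataFrame(
            {
                "date": dates,
                "depth_m": depth_m,
                "mean_temp_C": temps,
                "n_readings": 1,
            }
        )

    return _make


@pytest.fixture
def make_colony_table():
    """Factory for a colony-observation table from per-colony area dicts.

    ``colonies`` maps colony_id -> {month: live_area_cm2}; optional
    per-colony overrides for species/group/status/fractions.
    """

    def _make(colonies, species="O_franksi", group2005="bleached", extra=None):
        rows = []
        for cid, obs in colonies.items():
            for month, area in sorted(obs.items()):
                row = dict(
                    colony_id=cid,
                    species=species,
                    group2005=group2005,
                    month=month,
                    live_area_cm2=float(area),
                    frac_bleached=0.0,
                    frac_partial=0.0,
                    dead_area_cm2=0.0,
                    status="dead" if area == 0 else "alive",
                )
                if extra and cid in extra:
                    row.update(extra[cid])
                rows.append(row)
        return pd.DataFrame(rows)

    return _make
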