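import numpy as np
import pandas as pd
import pytest


def make_record(
    run="r1",
    condition="c1",
    sequence="AADRK",
    site_states=("H",),
    proteins="P1",
    proteotypic=True,
    charge=2,
    rt_min=30.0,
    intensity=1e6,
    pep=0.001,
    start=np.nan,
):
    return {
        "run": run,
        "condition": condition,
        "sequence": sequence,
        "site_states": tuple(site_states),
        "proteins": proteins,
        "proteotypic": proteotypic,
        "charge": charge,
        "rt_min": rt_min,
        "intensity": intensity,
        "pep": pep,
        "start": start,
    }


def records_frame(records):
    return pd.DataFrame(records)


@pytest.fixture
def single_run_hl_records():
    """One run: heavy single-Arg record (int 90) + CAV record (int 10)."""
    return records_frame(
        [
            make_record(sequence="AADRK", site_states=("H",), intensity=90.0),
            make_record(sequence="AAERK", site_states=("CAV",), intensity=10.0),
        ]
    )


@pytest.fixture
def pairing_records():
    """Ten records over four (sequence, run) groups yielding four pairs."""
    rows = [
        # S1 in two runs: all-H + single-CAV each -> 2 pairs
        make_record(run="r1", sequence="AADRK", site_states=("H",), intensity=70.0),
        make_record(run="r1", sequence="AADRK", site_states=("CAV",), intensity=10.0),
        make_record(run="r2", sequence="AADRK", site_states=("H",), intensity=80.0),
        make_record(run="r2", sequence="AADRK", site_states=("CAV",), intensity=20.0),
        # S2 with two Arg sites: all-H + two single-CAV variants -> 2 pairs
        make_record(run="r1", sequence="ARDRK", site_states=("H", "H"), intensity=60.0),
        make_record(run="r1", sequence="ARDRK", site_states=("CAV", "H"), intensity=6.0),
        make_record(run="r1", sequence="ARDRK", site_states=("H", "CAV"), intensity=4.0),
        make_record(run="r1", sequence="ARDRK", site_states=("CAV", "CAV"), intensity=1.0),
        # CAV-only group: no heavy partner
        make_record(run="r1", sequence="TTTRK", site_states=("CAV",), intensity=5.0),
        # light-Arg record: never paired
        make_record(run="r1", sequence="GGGRK", site_states=("L",), intensity=9.0),
    ]
    return records_frame(rows)
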