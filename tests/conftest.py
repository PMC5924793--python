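import numpy as np
import pandas as pd
import pytest

from splinetests.data_model import LongitudinalTable


def make_table(rows, categories=()):
    """rows: iterable of (subject, x, y) or (subject, x, y, {cat: label})."""
    records = []
    for row in rows:
        rec = {"subject": row[0], "x": row[1], "y": row[2]}
        if len(row) > 3:
            rec.update(row[3])
        records.append(rec)
    return LongitudinalTable(pd.DataFrame.from_records(records), list(categories))


@pytest.fixture
def two_clean_groups():
    """5 + 5 subjects, 6 timepoints each, labelled in category 'abx'."""
    rng = np.random.default_rng(42)
    rows = []
    for g, label in enumerate(["yes", "no"]):
        for s in range(5):
            sid = f"{label}{s}"
            for x in np.linspace(0, 10, 6):
                rows.append((sid, x, float(rng.normal(g, 1.0)), {"abx": label}))
    return make_table(rows, ["abx"])


@pytest.fixture
def tsv_file(tmp_path):
    path = tmp_path / "obs.tsv"
    path.write_text(
        "subject\tmonth\tabundance\tabx\n"
        "S1\t1\t0.5\tyes\n"
        "S1\t2\t0.6\tyes\n"
        "S2\t1\t0.1\tno\n"
        "S2\t3\t0.2\tno\n"
    )
    return path
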