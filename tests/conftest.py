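import numpy as np
import pytest

from csrec.cohort_io import CodeLevel, Cohort, Visit, Vocabulary


def make_visit(sid, idx, diags, procs=(), meds=()):
    return Visit(subject_id=sid, visit_index=idx,
                 diagnoses=frozenset(diags), procedures=frozenset(procs),
                 medications=frozenset(meds))


@pytest.fixture
def toy_cohort():
    """Three patients, mixed visit counts, small shared vocabulary."""
    patients = [
        ("p1", [make_visit("p1", 0, {"d1", "d2"}, {"pr1"}, {"mA", "mB"}),
                make_visit("p1", 1, {"d2", "d3"}, {"pr2"}, {"mA", "mB", "mC"})]),
        ("p2", [make_visit("p2", 0, {"d1"}, set(), {"mB"}),
                make_visit("p2", 1, {"d3"}, {"pr1", "pr2"}, set()),
                make_visit("p2", 2, {"d1", "d3"}, {"pr1"}, {"mC"})]),
        ("p3", [make_visit("p3", 0, {"d4"}, {"pr3"}, {"mA"})]),
    ]
    return Cohort(patients=patients, level=CodeLevel.ATC04)


@pytest.fixture
def toy_vocab():
    return Vocabulary(
        diag_index={f"d{i}": i - 1 for i in range(1, 5)},
        proc_index={f"pr{i}": i - 1 for i in range(1, 4)},
        med_index={"mA": 0, "mB": 1, "mC": 2},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
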