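"""Shared fixtures: published confusion tables and a matched fixture cohort."""

from __future__ import annotations

import pytest

from romadx import Cohort, MenopausalStatus, PatientRecord, Pathology

# Published confusion tables (tp, fp, fn, tn) per stratum and marker, together
# with the cutoff each was thresholded at (score >= cutoff is positive).
PRINTED_TABLES = {
    ("total", "ca125"): {"ct": (37, 18, 6, 38), "cutoff": 22.5},
    ("total", "he4"): {"ct": (30, 5, 13, 51), "cutoff": 73.0},
    ("total", "roma"): {"ct": (32, 2, 11, 54), "cutoff": 18.3},
    ("premenopause", "ca125"): {"ct": (16, 13, 5, 34), "cutoff": 35.0},
    ("premenopause", "he4"): {"ct": (12, 2, 9, 45), "cutoff": 75.0},
    ("premenopause", "roma"): {"ct": (16, 7, 5, 40), "cutoff": 11.5},
    ("postmenopause", "ca125"): {"ct": (19, 0, 3, 9), "cutoff": 25.0},
    ("postmenopause", "he4"): {"ct": (16, 0, 6, 9), "cutoff": 100.0},
    ("postmenopause", "roma"): {"ct": (18, 0, 4, 9), "cutoff": 25.5},
    ("early_stage", "roma"): {"ct": (9, 2, 3, 54), "cutoff": 18.3},
    ("advanced_stage", "roma"): {"ct": (23, 2, 8, 54), "cutoff": 18.3},
}

# Marker values realising each joint classification pattern at the total-
# cohort cutoffs (CA125 >= 22.5, HE4 >= 73, ROMA >= 18.3).  The ROMA call is
# genuinely computed from (he4, ca125, status), so each pattern needs a
# status under which it is attainable: a pre-menopausal ROMA-positive forces
# HE4 >~ 82, hence the infeasible pre patterns are realised post-menopausally.
_PATTERN_VALUES: dict[tuple[bool, bool, bool], tuple[str, float, float]] = {
    # (ca_pos, he_pos, roma_pos): (status, ca125, he4)
    (True, True, True): ("post", 50.0, 200.0),
    (True, True, False): ("pre", 30.0, 74.0),
    (True, False, True): ("post", 7000.0, 70.0),
    (True, False, False): ("post", 30.0, 30.0),
    (False, True, True): ("pre", 20.0, 100.0),
    (False, True, False): ("pre", 10.0, 74.0),
    (False, False, True): ("post", 22.0, 70.0),
    (False, False, False): ("pre", 10.0, 30.0),
}

# FIGO stages for the 43 malignant fixture patients (published distribution).
_STAGES = [1] * 4 + [2] * 8 + [3] * 22 + [4] * 9


def _patterns(n: int, ca_pos: int, he_pos: int, roma_pos: int):
    """Joint (ca, he, roma) call patterns with the requested margins."""
    out = []
    for i in range(n):
        out.append((i < ca_pos, i < he_pos, i < roma_pos))
    return out


def build_table3_cohort() -> Cohort:
    """99-patient cohort whose marker calls at the published total-cohort
    cutoffs reproduce all three printed confusion tables simultaneously."""
    records = []
    idx = 0
    for pathology, n, margins in (
        (Pathology.BENIGN, 56, (18, 5, 2)),
        (Pathology.MALIGNANT, 43, (37, 30, 32)),
    ):
        for k, pattern in enumerate(_patterns(n, *margins)):
            status, ca125, he4 = _PATTERN_VALUES[pattern]
            idx += 1
            records.append(
                PatientRecord(
                    id=f"F{idx:03d}",
                    age=60.0 if status == "post" else 35.0,
                    menopausal_status=MenopausalStatus(status),
                    ca125=ca125,
                    he4=he4,
                    pathology=pathology,
                    stage=_STAGES[k] if pathology is Pathology.MALIGNANT else None,
                )
            )
    return Cohort(records, provenance="table3-fixture")


@pytest.fixture(scope="session")
def table3_cohort() -> Cohort:
    return build_table3_cohort()


@pytest.fixture
def tiny_cohort() -> Cohort:
    """Three hand-written records covering both statuses and pathologies."""
    return Cohort(
        [
            PatientRecord("a", 35.0, MenopausalStatus.PRE, 17.0, 47.0, Pathology.BENIGN),
            PatientRecord(
                "b", 62.0, MenopausalStatus.POST, 121.0, 114.0, Pathology.MALIGNANT, stage=3
            ),
            PatientRecord(
                "c", 44.0, MenopausalStatus.PRE, 80.0, 90.0, Pathology.MALIGNANT, stage=1
            ),
        ],
        provenance="tiny",
    )
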