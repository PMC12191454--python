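"""Shared fixtures: reconstructed cohort margins and small report sets.

The published rule tables print, for each single-antecedent rule against
bradycardia in an N = 1611 cohort: support (4 dp), confidence (3 dp),
coverage (4 dp), lift (3 dp) and the joint count.  Those five numbers
over-determine the underlying 2x2 table, so the antecedent marginal is
recoverable as round(count / confidence) and the consequent marginal as the
unique integer making confidence / lift constant across rows (209).  The
reconstruction is itself verified by a dedicated test
(test_rules.test_reconstructed_marginals_are_consistent).
"""

from __future__ import annotations

import pytest

from pvsignal import (
    CohortSpec,
    ReportSet,
    SafetyReport,
    build_transactions,
    generate_exact,
    load_bundled_spec,
)
from pvsignal.reports import SourceKind

N_COHORT = 1611
CONSEQUENT_COUNT = 209  # rule-implied bradycardia marginal (Table-3 raw count: 199)

# label -> (antecedent_count, joint_count, support4, confidence3, coverage4,
#           lift3, odds_ratio2, ci_low2, ci_high2, significant)
ADE_ROWS = {
    "syncope": (18, 11, 0.0068, 0.611, 0.011, 4.711, 11.04, 3.86, 33.97, True),
    "loss of consciousness": (27, 14, 0.0087, 0.519, 0.017, 3.997, 7.65, 3.28, 17.98, True),
    "cardiac arrest": (119, 44, 0.0273, 0.370, 0.074, 2.850, 4.71, 3.06, 7.19, True),
    "hypotension": (128, 46, 0.0286, 0.359, 0.079, 2.770, 4.54, 2.98, 6.85, True),
    "overdose": (33, 10, 0.0062, 0.303, 0.020, 2.336, 3.01, 1.26, 6.69, True),
    "drug interaction": (61, 17, 0.0106, 0.279, 0.038, 2.148, 2.73, 1.43, 4.99, True),
    "product administered to patient of inappropriate age":
        (47, 11, 0.0068, 0.234, 0.029, 1.804, 2.11, 0.95, 4.32, False),
    "cardio-respiratory arrest": (43, 10, 0.0062, 0.233, 0.027, 1.793, 2.08, 0.90, 4.41, False),
    "respiratory arrest": (74, 15, 0.0093, 0.203, 0.046, 1.562, 1.76, 0.91, 3.22, False),
}

DDI_ROWS = {
    "lactated ringer's solution": (17, 12, 0.0074, 0.706, 0.011, 5.441, 16.96, 5.49, 62.19, True),
    "bupivacaine": (31, 12, 0.0074, 0.387, 0.019, 2.984, 4.43, 1.93, 9.78, True),
    "risperidone": (38, 12, 0.0074, 0.316, 0.024, 2.434, 3.22, 1.46, 6.74, True),
    "albuterol": (52, 13, 0.0081, 0.250, 0.032, 1.927, 2.32, 1.11, 4.53, True),
    "potassium chloride": (68, 14, 0.0087, 0.206, 0.042, 1.587, 1.79, 0.90, 3.35, False),
    "haloperidol": (83, 17, 0.0106, 0.205, 0.052, 1.579, 1.79, 0.96, 3.17, False),
    "sevoflurane": (107, 21, 0.0130, 0.196, 0.066, 1.513, 1.71, 0.98, 2.86, False),
}

# pathway -> (overlap k, size K, fold enrichment at 2 dp)
TABLE8_ROWS = {
    "Ribosome": (20, 130, 8.22),
    "Circadian rhythm": (4, 34, 6.29),
    "Cardiac muscle contraction": (8, 87, 4.92),
    "Oxidative phosphorylation": (12, 133, 4.82),
    "Mitophagy-animal": (6, 68, 4.72),
    "Acute myeloid leukemia": (6, 70, 4.58),
    "Parkinson's disease": (21, 262, 4.28),
    "Chemical carcinogenesis-ROS": (17, 220, 4.13),
    "Hypertrophic cardiomyopathy": (7, 91, 4.11),
    "Coronavirus disease-COVID-19": (18, 235, 4.09),
}
ENRICH_LIST_SIZE = 248
ENRICH_BACKGROUND = 13256


@pytest.fixture(scope="session")
def paper_spec() -> CohortSpec:
    """The bundled exact-marginal spec encoding all 16 printed rule rows."""
    return load_bundled_spec()

@pytest.fixture(scope="session")
def paper_cohort(paper_spec):
    """Deduplicated exact-marginal cohort realizing the printed margins."""
    from pvsignal import deduplicate

    rs = generate_exact(paper_spec)
    deduped, _ = deduplicate(rs)
    return deduped


@pytest.fixture(scope="session")
def paper_db(paper_cohort):
    return build_transactions(paper_cohort)


def make_report(case_id="C1", ades=("nausea",), drugs=("dexmedetomidine",),
                source=SourceKind.DIRECT, date=None, products=()):
    return SafetyReport(
        case_id=case_id,
        source_kind=source,
        suspect_products=list(products),
        suspect_active_ingredients=list(drugs),
        adverse_events=list(ades),
        received_date=date,
    )


@pytest.fixture
def small_reports() -> ReportSet:
    return ReportSet(
        [
            make_report("C1", ades=("bradycardia", "syncope"), drugs=("dexmedetomidine", "bupivacaine")),
            make_report("C2", ades=("hypotension",), drugs=("dexmedetomidine",)),
            make_report("C3", ades=("nausea",), drugs=("midazolam",)),
            make_report("C4", ades=("bradycardia",), drugs=("dexmedetomidine", "risperidone")),
        ]
    )
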