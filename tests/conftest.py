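import numpy as np
import pytest

from metsdx import cohort, criteria, markers, synthdata


def make_record(**overrides) -> cohort.ParticipantRecord:
    """A fully populated, eligible reference subject."""
    base = dict(
        id="R1", sex=cohort.FEMALE, age=45, weight=72.0, height=1.60,
        bmi=None, wc=96.0, sbp=118.0, dbp=76.0, chol_total=190.0,
        hdl=48.0, tg=160.0, glu=95.0,
    )
    base.update(overrides)
    return cohort.ParticipantRecord(**base)


@pytest.fixture
def record():
    return make_record()


@pytest.fixture(scope="session")
def cohort10k():
    """Default synthetic cohort, shared across the session."""
    return synthdata.generate_cohort(synthdata.CohortSpec(n=10_000, seed=1))


@pytest.fixture(scope="session")
def prepared10k(cohort10k):
    """(records, panels, atp3 labels, idf labels) after filtering/derivation."""
    kept, _ = cohort.apply_eligibility(cohort10k)
    kept = [cohort.derive_anthropometrics(r) for r in kept]
    panels = [markers.compute_panel(r) for r in kept]
    atp3 = np.array([criteria.atp_iii(r).positive for r in kept])
    idf = np.array([criteria.idf(r).positive for r in kept])
    return kept, panels, atp3, idf


def write_cohort_file(tmp_path, rows, header=None):
    header = header or ("id,sex,age,weight_kg,height_m,bmi,wc_cm,sbp,dbp,"
                        "chol_mgdl,hdl_mgdl,tg_mgdl,glu_mgdl,"
                        "dx_diabetes,dx_hypertension,tx_tg,dx_chol")
    path = tmp_path / "cohort.csv"
    path.write_text("\n".join([header, *rows]) + "\n")
    return path
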