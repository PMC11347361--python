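import numpy as np
import pytest

from biasbound.simulate import MetaSimConfig, generate_meta_sample


@pytest.fixture
def heterogeneous_fixture():
    """Five-study log-RR fixture with visible heterogeneity.

    Cross-checked against an independent REML implementation; see
    tests/test_meta.py for the frozen reference values.
    """
    return [(0.05, 0.07), (0.42, 0.10), (-0.12, 0.12), (0.31, 0.09), (0.55, 0.15)]


def write_study_csv(path, rows, header="study_id,quantile,measure,point,ci_lower,ci_upper,outcome_prevalence,rare_outcome,tag"):
    path.write_text("\n".join([header] + rows) + "\n")
    return path


@pytest.fixture
def study_csv(tmp_path):
    """Synthetic five-study table with Q2-Q4 RR rows, three tagged 'owob'."""
    z = 1.959963984540054
    rows = []
    rng_idx = 0
    for i, (theta_q4, tag) in enumerate(
        [(0.16, "owob"), (0.11, "owob"), (0.13, "owob"), (0.15, "weight"), (0.12, "weight")],
        start=1,
    ):
        for q, theta in [("Q2", theta_q4 / 3), ("Q3", 2 * theta_q4 / 3), ("Q4", theta_q4)]:
            se = 0.04 + 0.01 * i
            lo, hi = float(np.exp(theta - z * se)), float(np.exp(theta + z * se))
            rows.append(f"S{i},{q},rr,{float(np.exp(theta))!r},{lo!r},{hi!r},,,{tag}")
        rng_idx += 1
    return write_study_csv(tmp_path / "studies.csv", rows)


@pytest.fixture
def scenario_csv(tmp_path):
    """Scenario table mirroring the three worked confounder scenarios.

    Depression: OR 1.44 (exposure side, p0 0.08) and OR 1.58 (outcome
    side, p0 0.5 conservative); overeating: r 0.28 on the exposure side;
    food insecurity: plain RRs 1.60 / 1.42.
    """
    path = tmp_path / "scenarios.csv"
    path.write_text(
        "name,exposure_assoc_type,exposure_assoc_value,exposure_p0,"
        "outcome_assoc_type,outcome_assoc_value,outcome_p0\n"
        "depression,rr,1.39,,rr,1.48,\n"
        "overeating,r,0.28,0.5,rr,1.49,\n"
        "food_insecurity,rr,1.60,,rr,1.42,\n"
    )
    return path


@pytest.fixture
def meta_sample_factory():
    def factory(k=5, theta=np.log(1.14), tau2=0.0, seed=0, se_range=(0.05, 0.3)):
        return generate_meta_sample(
            MetaSimConfig(k=k, theta=theta, tau2=tau2, se_range=se_range, seed=seed)
        )

    return factory
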