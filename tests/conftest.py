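import math

import pytest

import snpmeta as sm


@pytest.fixture(scope="session")
def fixture_records():
    return sm.load_fixture()


@pytest.fixture(scope="session")
def records_by_snp(fixture_records):
    by = {}
    for rec in fixture_records:
        by.setdefault(rec.snp_id, []).append(rec)
    return by


@pytest.fixture(scope="session")
def rs762551_units(records_by_snp):
    return sm.build_analysis_units(records_by_snp["rs762551"], model="recessive")


def brute_force_pool(pairs):
    """Independent direct-summation oracle for fixed/DL pooling.

    ``pairs`` is a list of (y, se) tuples.  Returns a dict with the fixed
    pooled mean, Q, tau2 and the random-effects pooled mean — computed with
    plain Python sums, no shared code with the package internals.
    """
    w = [1.0 / (se * se) for _, se in pairs]
    sw = sum(w)
    y_fixed = sum(wi * y for wi, (y, _) in zip(w, pairs)) / sw
    q = sum(wi * (y - y_fixed) ** 2 for wi, (y, _) in zip(w, pairs))
    df = len(pairs) - 1
    c = sw - sum(wi * wi for wi in w) / sw
    tau2 = max(0.0, (q - df) / c) if df >= 1 else 0.0
    w_star = [1.0 / (se * se + tau2) for _, se in pairs]
    y_random = sum(wi * y for wi, (y, _) in zip(w_star, pairs)) / sum(w_star)
    se_random = 1.0 / math.sqrt(sum(w_star))
    return {
        "y_fixed": y_fixed,
        "se_fixed": 1.0 / math.sqrt(sw),
        "q": q,
        "tau2": tau2,
        "y_random": y_random,
        "se_random": se_random,
    }
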