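"""Random-effects meta-correlation: per-project r, DL pooling, strength bands."""

import logging
import math
import subprocess

import numpy as np
import pandas as pd
import pytest

from topicscep import (
    GeneratorConfig,
    ProjectCorrelation,
    classify_strength,
    generate_outcomes,
    meta_correlation,
    pool_random_effects,
    project_correlations,
)


def hand_dl_pool(pairs):
    """Spreadsheet-style DerSimonian–Laird oracle, written independently.

    ``pairs`` is a list of (r, n). Returns (r_pooled, tau2) using plain
    ``math`` arithmetic only.
    """
    z = [0.5 * math.log((1 + r) / (1 - r)) for r, _ in pairs]
    v = [1.0 / (n - 3) for _, n in pairs]
    w = [1.0 / vi for vi in v]
    sw = sum(w)
    zbar = sum(wi * zi for wi, zi in zip(w, z)) / sw
    q = sum(wi * (zi - zbar) ** 2 for wi, zi in zip(w, z))
    k = len(pairs)
    tau2 = 0.0
    if k > 1:
        c = sw - sum(wi**2 for wi in w) / sw
        tau2 = max(0.0, (q - (k - 1)) / c)
    ws = [1.0 / (vi + tau2) for vi in v]
    z_pooled = sum(wi * zi for wi, zi in zip(ws, z)) / sum(ws)
    r_pooled = (math.exp(2 * z_pooled) - 1) / (math.exp(2 * z_pooled) + 1)
    return r_pooled, tau2


class TestProjectCorrelations:
    def test_perfect_linear_relation_gives_r_one(self):
        df = pd.DataFrame(
            {"project_id": "A", "x": np.arange(10.0), "y": 2 * np.arange(10.0) + 1}
        )
        (pc,) = project_correlations(df, ("x", "y"))
        assert pc.r == pytest.approx(1.0)
        assert pc.n == 10

    def test_independent_outcomes_correlate_near_zero(self):
        rng = np.random.default_rng(11)
        df = pd.DataFrame(
            {"project_id": "A", "x": rng.normal(size=4000), "y": rng.normal(size=4000)}
        )
        (pc,) = project_correlations(df, ("x", "y"))
        assert abs(pc.r) < 0.05

    def test_constant_outcome_project_excluded_with_warning(self, caplog):
        df = pd.DataFrame(
            {
                "project_id": ["A"] * 6 + ["B"] * 6,
                "x": list(range(6)) + list(range(6)),
                "y": [1.0] * 6 + [1, 2, 1, 3, 2, 4],
            }
        )
        with caplog.at_level(logging.WARNING):
            out = project_correlations(df, ("x", "y"))
        assert [c.project_id for c in out] == ["B"]
        assert "zero variance" in caplog.text

    def test_small_projects_filtered_and_pairwise_complete_deletion(self):
        df = pd.DataFrame(
            {
                "project_id": ["A"] * 3 + ["B"] * 8,
                "x": [1, 2, 3] + [1, 2, 3, 4, 5, 6, 7, np.nan],
                "y": [1, 2, 3] + [2, 2, 4, 5, 4, 7, 6, 9.0],
            }
        )
        (pc,) = project_correlations(df, ("x", "y"))
        assert pc.project_id == "B"
        assert pc.n == 7  # the NaN pair is dropped

    def test_no_eligible_project_raises(self):
        df = pd.DataFrame({"project_id": ["A"] * 3, "x": [1, 2, 3], "y": [1, 2, 3.0]})
        with pytest.raises(ValueError, match="no project eligible"):
            project_correlations(df, ("x", "y"))


class TestPooling:
    def test_single_project_identity(self):
        pooled = pool_random_effects([ProjectCorrelation("A", 0.42, 50)])
        assert pooled.r == pytest.approx(0.42)
        assert pooled.tau2 == 0.0
        assert pooled.k == 1

    def test_identical_projects_are_homogeneous(self):
        cs = [ProjectCorrelation(str(i), 0.5, 40) for i in range(6)]
        pooled = pool_random_effects(cs)
        assert pooled.r == pytest.approx(0.5)
        assert pooled.tau2 == 0.0

    @pytest.mark.parametrize(
        "pairs",
        [
            [(0.3, 20), (0.5, 50), (0.7, 12)],
            [(0.63, 500), (0.58, 80)],
            [(-0.2, 30), (0.4, 300), (0.1, 10)],
        ],
    )
    def test_matches_hand_spreadsheet_oracle(self, pairs):
        cs = [ProjectCorrelation(str(i), r, n) for i, (r, n) in enumerate(pairs)]
        pooled = pool_random_effects(cs)
        r_ref, tau2_ref = hand_dl_pool(pairs)
        assert pooled.r == pytest.approx(r_ref, abs=1e-12)
        assert pooled.tau2 == pytest.approx(tau2_ref, abs=1e-12)

    def test_matches_r_metafor_on_fixture(self, tmp_path):
        """Independent cross-check against the rma(..., method='DL') route."""
        pairs = [(0.41, 120), (0.55, 60), (0.33, 200), (0.62, 45)]
        cs = [ProjectCorrelation(str(i), r, n) for i, (r, n) in enumerate(pairs)]
        pooled = pool_random_effects(cs)
        script = tmp_path / "dl.R"
        script.write_text(
            "suppressMessages(library(metafor))\n"
            f"ri <- c({','.join(str(r) for r, _ in pairs)})\n"
            f"ni <- c({','.join(str(n) for _, n in pairs)})\n"
            "d <- escalc(measure='ZCOR', ri=ri, ni=ni)\n"
            "f <- rma(yi, vi, data=d, method='DL')\n"
            "cat(sprintf('%.12f %.12f\\n', as.numeric(f$b), f$tau2))\n"
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        )
        z_ref, tau2_ref = map(float, out.stdout.split())
        assert math.atanh(pooled.r) == pytest.approx(z_ref, abs=1e-9)
        assert pooled.tau2 == pytest.approx(tau2_ref, abs=1e-9)

    def test_invariant_to_project_ordering(self):
        pairs = [(0.2, 25), (0.45, 90), (0.6, 40), (0.35, 15)]
        cs = [ProjectCorrelation(str(i), r, n) for i, (r, n) in enumerate(pairs)]
        a = pool_random_effects(cs)
        b = pool_random_effects(list(reversed(cs)))
        assert a.r == pytest.approx(b.r, abs=1e-15)
        assert a.tau2 == pytest.approx(b.tau2, abs=1e-15)

    def test_pooled_r_within_project_range(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            rs = rng.uniform(-0.8, 0.8, size=rng.integers(2, 8))
            ns = rng.integers(5, 200, size=len(rs))
            cs = [ProjectCorrelation(str(i), float(r), int(n)) for i, (r, n) in enumerate(zip(rs, ns))]
            pooled = pool_random_effects(cs)
            assert min(rs) - 1e-12 <= pooled.r <= max(rs) + 1e-12

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            pool_random_effects([ProjectCorrelation("A", 0.2, 4), ProjectCorrelation("B", 0.2, 3)])


class TestStrength:
    @pytest.mark.parametrize(
        "r,label",
        [
            (0.43, "moderate"),
            (0.63, "strong"),
            (0.3, "moderate"),
            (0.5, "moderate"),
            (0.29, "weak"),
            (0.51, "strong"),
            (-0.63, "strong"),
            (0.0, "weak"),
        ],
    )
    def test_bands_with_inclusive_boundaries(self, r, label):
        assert classify_strength(r) == label

    def test_magnitude_above_one_rejected(self):
        with pytest.raises(ValueError):
            classify_strength(1.2)


def test_recovery_bias_below_monte_carlo_se():
    """Pooled estimate is unbiased for the generating correlation at defaults."""
    true_r = float(GeneratorConfig().outcome_correlations[0, 2])
    estimates = []
    cfg = GeneratorConfig()
    for rep in range(200):
        df = generate_outcomes(cfg, seed=20_000 + rep)
        estimates.append(meta_correlation(df, ("indexed_cep", "eq5d_utility")).r)
    estimates = np.asarray(estimates)
    bias = estimates.mean() - true_r
    mc_se = estimates.std(ddof=1) / np.sqrt(len(estimates))
    # the bound admits the O(1/n) Fisher-transformation bias alongside pure
    # Monte-Carlo noise
    assert abs(bias) <= max(2 * mc_se, 0.004)
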