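"""The seeded report generator: determinism, calibration and ground truth."""

from __future__ import annotations

import math

import numpy as np
import pytest

from pvsignal.synthetic import (
    DEFAULT_SIGNAL_RATES,
    GeneratorConfig,
    generate,
    write_fixture,
)


def _read_all(directory):
    return {p.name: p.read_bytes() for p in sorted(directory.iterdir())}


class TestDeterminism:
    def test_same_seed_byte_identical(self, tmp_path):
        cfg = GeneratorConfig(seed=3, n_reports={"SYNFLORIX": 150, "OTHER": 300})
        write_fixture(generate(cfg), tmp_path / "a")
        write_fixture(generate(GeneratorConfig(
            seed=3, n_reports={"SYNFLORIX": 150, "OTHER": 300})), tmp_path / "b")
        assert _read_all(tmp_path / "a") == _read_all(tmp_path / "b")

    def test_distinct_seeds_differ(self, tmp_path):
        n = {"SYNFLORIX": 150, "OTHER": 300}
        write_fixture(generate(GeneratorConfig(seed=3, n_reports=n)), tmp_path / "a")
        write_fixture(generate(GeneratorConfig(seed=4, n_reports=n)), tmp_path / "b")
        assert (_read_all(tmp_path / "a")["VAERSDATA.csv"]
                != _read_all(tmp_path / "b")["VAERSDATA.csv"])


@pytest.fixture(scope="module")
def big():
    return generate(GeneratorConfig(seed=11, n_reports={"SYNFLORIX": 20_000}))


class TestCalibration:

    @staticmethod
    def _within_3sigma(count, n, p):
        return abs(count - n * p) <= 3 * math.sqrt(n * p * (1 - p))

    def test_marginals_converge(self, big):
        """At n=20,000 every configured marginal lands within 3 sigma."""
        t = big.truth.reports
        n = len(t)
        assert self._within_3sigma(int(t["serious"].sum()), n, 0.49)
        assert self._within_3sigma(int((t["sex"] == "U").sum()), n, 0.254)
        assert self._within_3sigma(int(t["onset_days"].isna().sum()), n, 0.178)
        assert self._within_3sigma(int((t["age_group"] == "0-1").sum()), n, 1054 / 1704)
        hhe_rate = DEFAULT_SIGNAL_RATES["SYNFLORIX"]["Hypotonic-hyporesponsive episode"]
        n_hhe = big.truth.assignments["preferred_term"].eq(
            "Hypotonic-hyporesponsive episode").sum()
        assert self._within_3sigma(int(n_hhe), n, hhe_rate)

    def test_serious_count_in_binomial_99_interval_at_study_size(self):
        g = generate(GeneratorConfig(seed=5, n_reports={"SYNFLORIX": 1704}))
        n_serious = int(g.truth.reports["serious"].sum())
        half = 2.576 * math.sqrt(1704 * 0.49 * 0.51)
        assert abs(n_serious - 835) <= half + 0.5

    def test_onset_tail_heavier_than_median(self, big):
        onsets = big.truth.reports["onset_days"].dropna()
        assert onsets.median() <= 1.0
        assert onsets.mean() > 5 * max(onsets.median(), 0.5)

    def test_default_mixture_has_no_adolescents(self, big):
        assert (big.truth.reports["age_group"] == "11-18").sum() == 0

    def test_death_implies_serious_and_one_flag_per_serious(self, big):
        t = big.truth.reports
        assert not (t["death"] & ~t["serious"]).any()
        flags = big.data[["DIED", "L_THREAT", "HOSPITAL", "X_STAY", "DISABLE",
                          "BIRTH_DEFECT"]].eq("Y").sum(axis=1)
        assert (flags.to_numpy() == t["serious"].to_numpy().astype(int)).all()

    def test_pts_per_report_bounds(self, big):
        per_report = big.truth.assignments.groupby("report_id").size()
        assert per_report.min() >= 1 and per_report.max() <= 5
        assert len(per_report) == len(big.truth.reports)


class TestTruthRecord:
    def test_expected_ror_matches_enumeration_oracle(self):
        """Closed-form expected ROR equals a from-scratch enumeration over
        the generating probabilities (pooled comparator odds)."""
        cfg = GeneratorConfig(
            seed=0,
            n_reports={"A": 1000, "B": 3000, "C": 500},
            signal_base_probs={"Pallor": 0.01},
            true_ror_overrides={("A", "Pallor"): 7.0, ("B", "Pallor"): 2.0},
        )
        truth = generate(cfg).truth
        probs = {}
        for vax in ("A", "B", "C"):
            mult = {("A"): 7.0, ("B"): 2.0}.get(vax, 1.0)
            odds = (0.01 / 0.99) * mult
            probs[vax] = odds / (1 + odds)
        for target in ("A", "B"):
            rest = [v for v in ("A", "B", "C") if v != target]
            n_rest = sum(cfg.n_reports[v] for v in rest)
            p_rest = sum(cfg.n_reports[v] * probs[v] for v in rest) / n_rest
            oracle = (probs[target] / (1 - probs[target])) / (p_rest / (1 - p_rest))
            assert truth.expected_ror[(target, "Pallor")] == pytest.approx(
                oracle, rel=1e-12)

    def test_override_on_odds_scale_is_exact_when_comparator_is_base(self):
        cfg = GeneratorConfig(
            seed=0,
            n_reports={"T": 100, "C": 100},
            signal_base_probs={"Pallor": 0.02},
            true_ror_overrides={("T", "Pallor"): 20.0},
        )
        assert cfg.expected_ror("T", "Pallor") == pytest.approx(20.0, rel=1e-12)


class TestEdgeConfigs:
    def test_empty_cohorts_yield_header_only_files(self, tmp_path):
        cfg = GeneratorConfig(seed=0, n_reports={"SYNFLORIX": 0})
        paths = write_fixture(generate(cfg), tmp_path)
        for key in ("data", "symptoms", "vax"):
            lines = paths[key].read_text().splitlines()
            assert len(lines) == 1  # header only

    def test_infeasible_configs_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(pts_per_report=(0, 0, 0, 0, 0))
        with pytest.raises(ValueError):
            GeneratorConfig(p_serious=1.5)
        with pytest.raises(ValueError):
            GeneratorConfig(true_ror_overrides={("X", "Nonexistent term"): 2.0})
        with pytest.raises(ValueError):
            GeneratorConfig(sex_probs=(0.5, 0.5, 0.5))

    def test_casing_noise_survives_canonicalization(self, tmp_path):
        from pvsignal import io as vio

        cfg = GeneratorConfig(seed=2, n_reports={"SYNFLORIX": 200, "OTHER": 200},
                              casing_noise=True)
        g = generate(cfg)
        paths = write_fixture(g, tmp_path)
        _, assignments = vio.assemble(
            vio.read_data_file(paths["data"]),
            vio.read_symptoms_file(paths["symptoms"]),
            vio.read_vax_file(paths["vax"]),
        )
        got = {(a.report_id, a.preferred_term.casefold()) for a in assignments}
        want = {(rid, pt.casefold())
                for rid, pt in g.truth.assignments.to_numpy()}
        assert got == want
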