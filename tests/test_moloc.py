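"""Multi-trait colocalization: ABFs, configuration enumeration, posteriors."""

import itertools
import math

import numpy as np
import pytest
from scipy import integrate, stats

from mrcoloc.exceptions import ConfigurationError, MissingVariantsError
from mrcoloc.moloc import (
    ColocPriors,
    Region,
    RegionIneligible,
    coloc_posteriors,
    enumerate_configurations,
    extract_region,
    wakefield_log_abf,
)
from mrcoloc.simulate import shared_causal_config, simulate_region
from mrcoloc.sumstats import SummaryStatsTable

from conftest import make_record, make_table


class TestWakefieldABF:
    def test_null_effect_shrinks(self):
        se, w = 0.1, 0.15
        got = wakefield_log_abf(0.0, se, w)
        assert got == pytest.approx(0.5 * math.log(se**2 / (se**2 + w**2)))
        assert got < 0

    def test_vacuous_prior_limit(self):
        assert wakefield_log_abf(0.3, 0.1, 1e-12) == pytest.approx(0.0, abs=1e-6)

    def test_matches_quadrature_oracle(self, rng):
        # logABF = log of the normal-normal marginal likelihood ratio,
        # integrated numerically
        for _ in range(10):
            beta = float(rng.normal(0, 0.3))
            se = float(rng.uniform(0.05, 0.3))
            w = float(rng.uniform(0.05, 0.5))

            def marginal(b):
                return stats.norm.pdf(beta, loc=b, scale=se) * stats.norm.pdf(
                    b, loc=0, scale=w
                )

            num, _ = integrate.quad(marginal, -10 * w, 10 * w, limit=200)
            denom = stats.norm.pdf(beta, loc=0, scale=se)
            assert wakefield_log_abf(beta, se, w) == pytest.approx(
                math.log(num / denom), abs=1e-6
            )

    def test_invalid_inputs(self):
        with pytest.raises(ConfigurationError):
            wakefield_log_abf(0.1, 0.0, 0.15)
        with pytest.raises(ConfigurationError):
            wakefield_log_abf(0.1, 0.1, -1.0)


def _partition_count_oracle(n):
    """Independent count of (subset, partition) configurations: for each
    non-empty subset, the Bell number via explicit enumeration of
    assignments to blocks."""

    def bell(k):
        # count set partitions by generating canonical block assignments
        count = 0
        for assign in itertools.product(range(k), repeat=k):
            # canonical: block labels appear in first-use order
            seen = []
            ok = True
            for a in assign:
                if a not in seen:
                    if a != len(seen):
                        ok = False
                        break
                    seen.append(a)
            if ok:
                count += 1
        return count

    total = 1  # null
    for size in range(1, n + 1):
        total += math.comb(n, size) * bell(size)
    return total


class TestEnumerateConfigurations:
    @pytest.mark.parametrize("n, expected", [(1, 2), (2, 5), (3, 15)])
    def test_counts_match_partition_oracle(self, n, expected):
        configs = enumerate_configurations(n)
        assert len(configs) == expected
        assert len(configs) == _partition_count_oracle(n)
        assert len({c.label for c in configs}) == len(configs)

    def test_three_trait_labels(self):
        labels = {c.label for c in enumerate_configurations(3)}
        assert labels == {
            "null", "a", "b", "c", "a.b", "a.c", "b.c", "ab", "ac", "bc",
            "ab.c", "ac.b", "bc.a", "a.b.c", "abc",
        }

    def test_out_of_range(self):
        for n in (0, 7):
            with pytest.raises(ConfigurationError):
                enumerate_configurations(n)


def _toy_region(betas, ses, trait_types=None, min_variants=1):
    """Region over len(betas[0]) variants and len(betas) traits."""
    n_traits = len(betas)
    n_var = len(betas[0])
    trait_types = trait_types or ["quantitative"] * n_traits
    tables = {}
    for t in range(n_traits):
        recs = [
            make_record(
                variant_id=f"rs{v}", pos=1000 + v, eaf=0.3,
                beta=betas[t][v], se=ses[t][v],
                pvalue=float(2 * stats.norm.sf(abs(betas[t][v] / ses[t][v]))) or 1e-300,
            )
            for v in range(n_var)
        ]
        name = "abcdef"[t]
        tables[name] = SummaryStatsTable.from_records(
            recs, name, trait_types[t],
            n_case=5000 if trait_types[t] == "binary" else None,
            n_control=5000 if trait_types[t] == "binary" else None,
        )
    return Region(center_variant="rs0", window=10**6, tables=tables,
                  min_variants=min_variants)


def _brute_force_posteriors(labf, priors):
    """Explicit enumeration oracle: every configuration x admissible variant
    assignment, in plain floats."""
    n_traits = len(labf)
    n_var = len(labf[0])
    weights = {}
    for cfg in enumerate_configurations(n_traits):
        if not cfg.groups:
            weights[cfg.label] = 1.0
            continue
        total = 0.0
        for assign in itertools.product(range(n_var), repeat=len(cfg.groups)):
            if len(set(assign)) != len(assign):
                continue
            term = 1.0
            for g, v in zip(cfg.groups, assign):
                term *= priors.for_size(len(g))
                for t in g:
                    term *= math.exp(labf[t][v])
            total += term
        weights[cfg.label] = total
    z = sum(weights.values())
    return {k: v / z for k, v in weights.items()}


class TestColocPosteriors:
    def test_all_null_z_scores_favor_null(self, rng):
        n = 30
        betas = [list(rng.normal(0, 0.01, n)) for _ in range(3)]
        ses = [[0.1] * n for _ in range(3)]
        region = _toy_region(betas, ses)
        res = coloc_posteriors(region)
        assert res.posterior["null"] > 0.99

    def test_strong_shared_variant_gives_high_full_share(self, rng):
        n = 40
        betas = [list(rng.normal(0, 0.01, n)) for _ in range(3)]
        for t in range(3):
            betas[t][7] = 1.0  # |z| = 10 in every trait
        ses = [[0.1] * n for _ in range(3)]
        res = coloc_posteriors(_toy_region(betas, ses))
        assert res.ppa_full_share >= 0.80

    def test_matches_bruteforce_enumeration_on_toy_region(self, rng):
        n = 8
        betas = [list(rng.normal(0, 0.3, n)) for _ in range(3)]
        ses = [list(rng.uniform(0.05, 0.2, n)) for _ in range(3)]
        region = _toy_region(betas, ses)
        priors = ColocPriors()
        res = coloc_posteriors(region, priors)
        labf = [
            [wakefield_log_abf(betas[t][v], ses[t][v], 0.15) for v in range(n)]
            for t in range(3)
        ]
        oracle = _brute_force_posteriors(labf, priors)
        for label, want in oracle.items():
            assert res.posterior[label] == pytest.approx(want, abs=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_posteriors_normalize(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 60))
        betas = [list(rng.normal(0, 0.2, n)) for _ in range(3)]
        ses = [list(rng.uniform(0.05, 0.3, n)) for _ in range(3)]
        res = coloc_posteriors(_toy_region(betas, ses))
        assert sum(res.posterior.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(p >= 0 for p in res.posterior.values())

    def test_two_trait_case_equals_classic_coloc(self, rng):
        # independent implementation of the classic 5-hypothesis two-trait
        # colocalization (H0..H4) on the same ABFs
        n = 25
        betas = [list(rng.normal(0, 0.2, n)) for _ in range(2)]
        betas[0][4] = 0.9
        betas[1][4] = 0.8
        ses = [list(rng.uniform(0.05, 0.2, n)) for _ in range(2)]
        priors = ColocPriors(p1=1e-4, p2=1e-6, p3=1e-7)
        res = coloc_posteriors(_toy_region(betas, ses), priors)

        l1 = np.array([wakefield_log_abf(betas[0][v], ses[0][v], 0.15) for v in range(n)])
        l2 = np.array([wakefield_log_abf(betas[1][v], ses[1][v], 0.15) for v in range(n)])
        a1 = np.exp(l1)
        a2 = np.exp(l2)
        h0 = 1.0
        h1 = 1e-4 * a1.sum()
        h2 = 1e-4 * a2.sum()
        h3 = 1e-8 * (a1.sum() * a2.sum() - (a1 * a2).sum())
        h4 = 1e-6 * (a1 * a2).sum()
        z = h0 + h1 + h2 + h3 + h4
        assert res.posterior["null"] == pytest.approx(h0 / z, abs=1e-9)
        assert res.posterior["a"] == pytest.approx(h1 / z, abs=1e-9)
        assert res.posterior["b"] == pytest.approx(h2 / z, abs=1e-9)
        assert res.posterior["a.b"] == pytest.approx(h3 / z, abs=1e-9)
        assert res.posterior["ab"] == pytest.approx(h4 / z, abs=1e-9)

    def test_variant_order_permutation_invariant(self, rng):
        n = 12
        betas = [list(rng.normal(0, 0.3, n)) for _ in range(3)]
        ses = [list(rng.uniform(0.05, 0.2, n)) for _ in range(3)]
        res1 = coloc_posteriors(_toy_region(betas, ses))
        perm = list(rng.permutation(n))
        res2 = coloc_posteriors(_toy_region(
            [[b[i] for i in perm] for b in betas],
            [[s[i] for i in perm] for s in ses],
        ))
        for label, p in res1.posterior.items():
            assert res2.posterior[label] == pytest.approx(p, abs=1e-12)

    def test_full_share_ppa_monotone_in_p3(self, rng):
        n = 20
        betas = [list(rng.normal(0, 0.1, n)) for _ in range(3)]
        for t in range(3):
            betas[t][3] = 0.5
        ses = [[0.1] * n for _ in range(3)]
        region = _toy_region(betas, ses)
        ppas = [
            coloc_posteriors(region, ColocPriors(p1=1e-4, p2=1e-6, p3=p3)).ppa_full_share
            for p3 in (1e-8, 1e-7, 1e-6)
        ]
        assert ppas[0] <= ppas[1] <= ppas[2]

    def test_binary_trait_uses_wider_prior(self, rng):
        n = 10
        betas = [list(rng.normal(0, 0.2, n)) for _ in range(2)]
        ses = [[0.1] * n for _ in range(2)]
        res_q = coloc_posteriors(_toy_region(betas, ses))
        res_b = coloc_posteriors(
            _toy_region(betas, ses, trait_types=["quantitative", "binary"]))
        assert res_q.posterior != res_b.posterior
        # explicit override restores equality
        res_o = coloc_posteriors(
            _toy_region(betas, ses, trait_types=["quantitative", "binary"]),
            prior_sd={"b": 0.15},
        )
        for label, p in res_q.posterior.items():
            assert res_o.posterior[label] == pytest.approx(p, abs=1e-12)


class TestExtractRegion:
    def _tables(self, n=60, drop_center_in=None, low_maf=False):
        tables = []
        for name in ("a", "b", "c"):
            recs = []
            for v in range(n):
                if drop_center_in == name and v == n // 2:
                    continue
                recs.append(make_record(
                    variant_id=f"rs{v}", chrom="12", pos=10**6 + v * 1000,
                    eaf=0.005 if (low_maf and v < 15) else 0.3,
                    beta=0.01, se=0.05, pvalue=0.8,
                ))
            tables.append(SummaryStatsTable.from_records(recs, name, "quantitative"))
        return tables, f"rs{n // 2}"

    def test_eligible_region(self):
        tables, center = self._tables(60)
        region = extract_region(tables, center)
        assert isinstance(region, Region)
        assert region.n_variants == 60

    def test_too_few_variants(self):
        tables, center = self._tables(49)
        region = extract_region(tables, center)
        assert isinstance(region, RegionIneligible)
        assert region.reason == "min_variants"

    def test_maf_filter_counts_against_eligibility(self):
        tables, center = self._tables(60, low_maf=True)
        region = extract_region(tables, center)
        assert isinstance(region, RegionIneligible)
        assert region.reason == "min_variants"

    def test_center_missing_from_one_trait(self):
        tables, center = self._tables(60, drop_center_in="c")
        region = extract_region(tables, center)
        assert isinstance(region, RegionIneligible)
        assert region.reason == "lead variant absent"

    def test_center_absent_everywhere_is_lookup_error(self):
        tables, _ = self._tables(10)
        with pytest.raises(MissingVariantsError):
            extract_region(tables, "rs_nowhere")

    def test_window_restricts_variants(self):
        tables, center = self._tables(60)
        region = extract_region(tables, center, window=5_000, min_variants=5)
        assert isinstance(region, Region)
        assert region.n_variants == 11  # center +/- 5 variants at 1 kb spacing

    def test_simulated_shared_causal_region_colocalizes(self):
        cfg, causal = shared_causal_config(n_variants=120)
        tables, _, _ = simulate_region(cfg, seed=11)
        lead = tables["exposure"].variant_ids[causal]
        region = extract_region(list(tables.values()), lead)
        assert isinstance(region, Region)
        res = coloc_posteriors(region)
        assert res.ppa_full_share >= 0.80
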