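import dataclasses

import numpy as np
import pandas as pd
import pytest

from dhqtl.linkage import GenotypeMatrix
from dhqtl.qtl import (
    QtlScan,
    ScanOptions,
    cofactor_scan,
    find_hits,
    icim_scan,
    interval_mapping,
    name_and_report,
    name_hits,
    permutation_threshold,
    single_marker_lod,
)
from dhqtl.simulate import default_config, simulate_study


def qtl_config(d=6.0, position=40.0, length=100.0, n_markers=11, n_lines=157,
               env=25.0, seed=0):
    return default_config(
        n_lines=n_lines, n_reps=1, plants_per_line_rep=1,
        chromosomes=(("C1", length, n_markers),),
        major_genes=(("C1", position, d),), epistasis=(),
        polygene_variance=0.0, env_variance=env, seed=seed,
    )


def marker_anova_oracle(y, x):
    """Two-group decomposition: LOD and R^2 from class means."""
    y = np.asarray(y, float)
    a, b = y[x == 1], y[x == -1]
    n = y.size
    rss0 = ((y - y.mean()) ** 2).sum()
    pred = np.where(x == 1, a.mean(), b.mean())
    rss1 = ((y - pred) ** 2).sum()
    lod = (n / 2) * np.log10(rss0 / rss1)
    return lod, (b.mean() - a.mean()) / 2, 1 - rss1 / rss0


class TestSingleMarker:
    def test_constant_phenotype(self, rng):
        x = rng.choice(["a", "b"], size=30)
        lod, add, r2 = single_marker_lod(np.ones(30), x)
        assert lod == 0.0 and r2 == 0.0

    def test_perfect_separation(self, rng):
        x = np.where(rng.random(40) < 0.5, "a", "b")
        y = np.where(x == "a", 1.0, -1.0)
        lod, add, r2 = single_marker_lod(y, x)
        assert r2 == pytest.approx(1.0)
        assert add == pytest.approx(-1.0)  # 'b' class mean minus 'a', halved

    def test_matches_anova_oracle(self, rng):
        for _ in range(10):
            x = np.where(rng.random(60) < 0.5, 1.0, -1.0)
            y = 2.0 * x + rng.normal(size=60)
            lod, add, r2 = single_marker_lod(y, x)
            o_lod, o_add, o_r2 = marker_anova_oracle(y, x)
            assert lod == pytest.approx(o_lod, abs=1e-10)
            assert add == pytest.approx(o_add, abs=1e-10)
            assert r2 == pytest.approx(o_r2, abs=1e-10)

    def test_monomorphic_error(self):
        with pytest.raises(ValueError, match="monomorphic"):
            single_marker_lod(np.arange(5.0), np.array(["a"] * 5))


class TestIntervalMapping:
    def test_reduces_to_marker_regression_at_markers(self):
        study = simulate_study(qtl_config(seed=21))
        y = study.line_means().to_numpy()
        profile = interval_mapping(y, study.genotypes, study.gmap)
        assert (profile["lod"] >= 0).all()
        assert profile["lod"].notna().all()
        for marker, pos in zip(study.gmap.markers, study.gmap.positions("C1")):
            row = profile[np.isclose(profile["cm"], pos)].iloc[0]
            m_lod, m_add, m_r2 = single_marker_lod(y, study.genotypes.column(marker))
            assert row["lod"] == pytest.approx(m_lod, abs=1e-6)
            assert row["add"] == pytest.approx(m_add, abs=1e-4)
            assert row["r2"] == pytest.approx(m_r2, abs=1e-6)

    def test_peak_near_true_locus(self):
        hits_within = 0
        runs = 30
        for i in range(runs):
            # d=6, env 25: R^2 = 36/61 ~ 0.15 at n=157
            study = simulate_study(qtl_config(seed=400 + i))
            y = study.line_means().to_numpy()
            profile = interval_mapping(y, study.genotypes, study.gmap)
            peak = profile.loc[profile["lod"].idxmax()]
            hits_within += abs(peak["cm"] - 40.0) <= 10.0
        assert hits_within >= 0.8 * runs

    def test_null_stays_below_threshold(self):
        below = 0
        runs = 30
        for i in range(runs):
            study = simulate_study(qtl_config(d=0.0, seed=800 + i))
            y = study.line_means().to_numpy()
            opts = ScanOptions(n_permutations=200, seed=i)
            thr = permutation_threshold(y, study.genotypes, options=opts)
            profile = interval_mapping(y, study.genotypes, study.gmap)
            below += profile["lod"].max() < thr
        assert below >= 0.9 * runs

    def test_missing_data_falls_back_to_nearest_informative(self):
        study = simulate_study(
            dataclasses.replace(qtl_config(seed=31), missing_rate=0.15)
        )
        y = study.line_means().to_numpy()
        profile = interval_mapping(y, study.genotypes, study.gmap)
        assert profile["lod"].notna().all()
        assert (profile["lod"] >= 0).all()


class TestCofactorScan:
    def test_empty_cofactors_equal_plain_im(self):
        study = simulate_study(qtl_config(seed=51))
        y = study.line_means().to_numpy()
        a = interval_mapping(y, study.genotypes, study.gmap)
        b = cofactor_scan(y, study.genotypes, study.gmap, [])
        pd.testing.assert_frame_equal(a, b)

    def test_window_rule_excludes_nearby_cofactor(self):
        # a cofactor inside the exclusion window must not change the
        # LOD at the evaluated position relative to no cofactors at all
        study = simulate_study(qtl_config(d=0.0, seed=52))
        y = study.line_means().to_numpy()
        plain = interval_mapping(y, study.genotypes, study.gmap)
        near = cofactor_scan(y, study.genotypes, study.gmap, ["M0005"])
        pos = study.gmap.positions("C1")[4]  # M0005 at 40 cM
        window = ScanOptions().cofactor_window_cm
        mask = (plain["cm"] - pos).abs() <= window
        assert np.allclose(
            plain.loc[mask, "lod"], near.loc[mask, "lod"], atol=1e-8
        )

    def test_unknown_and_exhaustive_cofactors_rejected(self):
        study = simulate_study(qtl_config(seed=53))
        y = study.line_means().to_numpy()
        with pytest.raises(ValueError, match="not on the map"):
            cofactor_scan(y, study.genotypes, study.gmap, ["nope"])
        with pytest.raises(ValueError, match="all markers"):
            cofactor_scan(y, study.genotypes, study.gmap, study.gmap.markers)

    def test_separates_linked_qtl_better_than_im(self):
        # two QTL 30 cM apart on one chromosome
        cfg = default_config(
            n_lines=200, n_reps=1, plants_per_line_rep=1,
            chromosomes=(("C1", 100.0, 21),),
            major_genes=(("C1", 30.0, 6.0), ("C1", 60.0, 6.0)),
            epistasis=(), polygene_variance=0.0, env_variance=16.0,
        )
        im_two, mqm_two = 0, 0
        runs = 25
        opts = ScanOptions(lod_threshold=3.0)
        for i in range(runs):
            study = simulate_study(dataclasses.replace(cfg, seed=1200 + i))
            y = study.line_means().to_numpy()
            im_prof = interval_mapping(y, study.genotypes, study.gmap, opts)
            im_two += len(find_hits(im_prof, study.gmap, opts)) >= 2
            cof = ["M0007", "M0013"]  # markers at the true loci
            mqm_prof = cofactor_scan(y, study.genotypes, study.gmap, cof, opts)
            mqm_two += len(find_hits(mqm_prof, study.gmap, opts)) >= 2
        assert mqm_two >= im_two


class TestIcim:
    def test_null_selects_nothing_and_matches_im(self):
        study = simulate_study(qtl_config(d=0.0, seed=61))
        y = study.line_means().to_numpy()
        profile, hits = icim_scan(y, study.genotypes, study.gmap)
        plain = interval_mapping(y, study.genotypes, study.gmap)
        # with p_in = 0.001 on null data, stepwise almost surely selects
        # nothing and the scan degenerates to plain interval mapping
        pd.testing.assert_frame_equal(profile, plain)
        assert len(hits) == 0

    def test_recovers_three_gene_architecture(self, study157):
        y = study157.line_means().to_numpy()
        profile, hits = icim_scan(y, study157.genotypes, study157.gmap)
        truth = {
            (chrom, pos) for chrom, pos, _ in study157.truth.major_genes
        }
        for chrom, pos in truth:
            near = hits[
                (hits["group"] == chrom) & ((hits["cm"] - pos).abs() <= 10.0)
            ]
            assert len(near) >= 1, f"missed locus {chrom}:{pos}"

    def test_hit_r2_bounds(self, study157):
        y = study157.line_means().to_numpy()
        _, hits = icim_scan(y, study157.genotypes, study157.gmap)
        assert ((hits["r2"] > 0) & (hits["r2"] < 1)).all()
        # combined model PVE at least the largest single-QTL PVE
        x = study157.genotypes.numeric()
        cols = []
        for row in hits.itertuples():
            markers = study157.gmap.group_markers(row.group)
            pos = study157.gmap.positions(row.group)
            j = int(np.argmin(np.abs(pos - row.cm)))
            cols.append(study157.genotypes.markers.index(markers[j]))
        design = np.column_stack([np.ones(y.size)] + [x[:, c] for c in cols])
        design = np.nan_to_num(design)
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ beta
        combined_pve = 1 - resid.var() / y.var()
        assert combined_pve >= hits["r2"].max() - 1e-9


class TestPermutationThreshold:
    def test_alpha_one_gives_minimum(self, study157):
        y = study157.line_means().to_numpy()
        opts = ScanOptions(n_permutations=100, alpha=1.0, seed=5)
        thr = permutation_threshold(y, study157.genotypes, options=opts)
        opts2 = ScanOptions(n_permutations=100, alpha=0.05, seed=5)
        thr2 = permutation_threshold(y, study157.genotypes, options=opts2)
        assert thr <= thr2  # monotone in alpha; alpha=1 is the minimum

    def test_seed_reproducible(self, study157):
        y = study157.line_means().to_numpy()
        opts = ScanOptions(n_permutations=150, seed=9)
        a = permutation_threshold(y, study157.genotypes, options=opts)
        b = permutation_threshold(y, study157.genotypes, options=opts)
        assert a == b

    def test_denser_map_never_lower_in_expectation(self):
        # max over a superset of markers dominates pathwise
        cfg = qtl_config(d=0.0, n_markers=21, seed=71)
        study = simulate_study(cfg)
        y = study.line_means().to_numpy()
        thin = GenotypeMatrix(study.genotypes.frame.iloc[:, ::2])
        diffs = []
        for s in range(10):
            opts = ScanOptions(n_permutations=150, seed=s)
            full = permutation_threshold(y, study.genotypes, options=opts)
            half = permutation_threshold(y, thin, options=opts)
            diffs.append(full - half)
        assert np.mean(diffs) >= 0

    def test_marker_agrees_with_im_method(self, study157):
        y = study157.line_means().to_numpy()
        opts = ScanOptions(n_permutations=100, seed=3, step=5.0)
        fast = permutation_threshold(y, study157.genotypes, options=opts)
        slow = permutation_threshold(
            y, study157.genotypes, study157.gmap, opts, method="im"
        )
        # IM grid max can only exceed the marker max, and only slightly
        assert slow >= fast - 1e-9
        assert slow - fast < 0.5

    def test_too_few_permutations(self, study157):
        y = study157.line_means().to_numpy()
        with pytest.raises(ValueError):
            permutation_threshold(
                y, study157.genotypes,
                options=ScanOptions(n_permutations=50),
            )


class TestReporting:
    def _toy_hits(self):
        return pd.DataFrame(
            {
                "group": ["C4", "C4"],
                "cm": [23.0, 80.0],
                "lod": [3.9, 5.5],
                "add": [8.3, 9.5],
                "r2": [0.086, 0.118],
                "support_lo": [20.0, 75.0],
                "support_hi": [26.0, 84.0],
                "left_marker": ["SF13319", "SF12597a"],
                "right_marker": ["Indel58", "SF11933"],
            }
        )

    def test_ordinal_naming(self):
        named = name_hits(self._toy_hits(), trait="Hsr")
        assert list(named["name"]) == ["Hsr 4.1", "Hsr 4.2"]

    def test_report_totals(self):
        report = name_and_report({"2011 (MQM)": self._toy_hits()})
        total = report[report["name"] == "total"]["r2"].iloc[0]
        assert total == pytest.approx(0.204)

    def test_empty_report(self):
        report = name_and_report({})
        assert report.empty

    def test_scan_model_object(self, study157):
        scan = QtlScan(study157.line_means(), study157.genotypes, study157.gmap)
        res = scan.fit(method="icim")
        assert res.method == "icim"
        assert {"name", "group", "cm", "lod", "r2"} <= set(res.hits.columns)
        assert res.total_pve > 0
        text = res.summary()
        assert "hits" in text and "LOD" in text

    def test_scan_options_validation(self):
        with pytest.raises(ValueError):
            ScanOptions(p_in=0.5, p_out=0.1)
        with pytest.raises(ValueError):
            ScanOptions(step=0.0)
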