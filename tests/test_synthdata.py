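import numpy as np
import pytest

from metintegrate import synthdata
from metintegrate.containers import CLASS_METASTASIS, CLASS_NORMAL, CLASS_PRIMARY
from metintegrate.errors import InvalidParameterError


class TestTissueExpression:
    def test_planted_shift_appears_in_metastasis_only(self):
        em, truth = synthdata.generate_tissue_expression(
            n_genes=1000, n_per_class=(10, 20, 10), n_de=50,
            effect_size=2.0, noise_sd=0.5, seed=7)
        assert em.values.shape == (1000, 40)
        met = em.class_samples(CLASS_METASTASIS)
        pt = em.class_samples(CLASS_PRIMARY)
        nrm = em.class_samples(CLASS_NORMAL)
        de = truth.de_gene_ids
        diff_met = (em.values.loc[de, met].mean(axis=1)
                    - em.values.loc[de, pt].mean(axis=1))
        # group-mean contrast ~ effect +/- 3*sd*sqrt(1/n_met + 1/n_pt)
        tol = 3 * 0.5 * np.sqrt(1 / 10 + 1 / 20)
        assert (np.abs(diff_met - 2.0) < tol).mean() > 0.99
        diff_pt = (em.values.loc[de, pt].mean(axis=1)
                   - em.values.loc[de, nrm].mean(axis=1))
        assert np.abs(diff_pt).max() < 3 * 0.5 * np.sqrt(1 / 20 + 1 / 10) + 0.2

    def test_truth_ids_resolve_and_count_matches(self):
        em, truth = synthdata.generate_tissue_expression(
            n_genes=200, n_per_class=(3, 3, 3), n_de=20, seed=1)
        assert len(truth.planted_de_genes) == 20
        assert set(truth.de_gene_ids) <= set(em.gene_ids)
        assert all(e != 0 and np.isfinite(e) for _, e in truth.planted_de_genes)

    def test_seed_determinism(self):
        em1, t1 = synthdata.generate_tissue_expression(
            n_genes=100, n_per_class=(3, 4, 5), n_de=10, seed=7)
        em2, t2 = synthdata.generate_tissue_expression(
            n_genes=100, n_per_class=(3, 4, 5), n_de=10, seed=7)
        assert em1.values.equals(em2.values)
        assert t1.planted_de_genes == t2.planted_de_genes

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_per_class": (1, 5, 5)},
            {"n_de": 999, "n_genes": 100},
            {"effect_size": 0.0},
            {"noise_sd": 0.0},
        ],
    )
    def test_bad_parameters_rejected(self, kwargs):
        with pytest.raises(InvalidParameterError):
            synthdata.generate_tissue_expression(n_genes=kwargs.pop("n_genes", 100),
                                                 **kwargs)


class TestCelllinePanel:
    def test_dependency_values_bimodal_and_in_range(self):
        _em, dep, truth = synthdata.generate_cellline_panel(
            n_lines=100, frac_metastatic_origin=0.4, n_genes=500,
            n_essential=30, seed=3)
        vals = dep.values.to_numpy()
        assert ((vals >= 0) & (vals <= 1)).all()
        mean_gd = dep.values.mean(axis=1)
        ess = truth.planted_essential_genes
        assert mean_gd.loc[ess].min() >= 0.9
        rest = mean_gd.drop(ess)
        assert rest.max() <= 0.2

    def test_no_essentials_means_low_dependency_everywhere(self):
        _em, dep, _t = synthdata.generate_cellline_panel(
            n_lines=60, frac_metastatic_origin=0.5, n_genes=300,
            n_essential=0, seed=4)
        assert dep.values.mean(axis=1).max() <= 0.2

    def test_origin_fraction_respected(self):
        _em, dep, _t = synthdata.generate_cellline_panel(
            n_lines=200, frac_metastatic_origin=0.3, n_genes=50,
            n_essential=0, seed=5)
        frac = (dep.origin == CLASS_METASTASIS).mean()
        assert frac == pytest.approx(0.3, abs=0.01)

    def test_planted_signature_is_coexpressed(self):
        em, _dep, truth = synthdata.generate_cellline_panel(
            n_lines=300, frac_metastatic_origin=0.4, n_genes=500,
            n_essential=0, seed=6, n_signature=30, signature_strength=1.0)
        sig = truth.planted_response_signature
        assert len(sig) == 30
        sub = em.values.loc[sig]
        corr = np.corrcoef(sub.to_numpy())
        off_diag = corr[np.triu_indices(30, k=1)]
        assert off_diag.mean() > 0.5  # shared latent activity

    def test_invalid_fraction_rejected(self):
        with pytest.raises(InvalidParameterError):
            synthdata.generate_cellline_panel(n_lines=10, frac_metastatic_origin=1.5)


@pytest.fixture(scope="module")
def panel():
    return synthdata.generate_cellline_panel(
        n_lines=400, frac_metastatic_origin=0.4, n_genes=300,
        n_essential=0, seed=8, n_signature=25, signature_strength=1.0)


class TestDrugResponse:
    def test_strong_coupling_gives_strong_anticorrelation(self, panel):
        em, _dep, truth = panel
        lfc = synthdata.generate_drug_response(
            em, truth.planted_response_signature, coupling=1.0,
            noise_sd=0.1, seed=1)
        score = em.values.loc[truth.planted_response_signature].mean(axis=0)
        r = np.corrcoef(score, lfc)[0, 1]
        assert r <= -0.9

    def test_zero_coupling_decouples(self, panel):
        em, _dep, truth = panel
        lfc = synthdata.generate_drug_response(
            em, truth.planted_response_signature, coupling=0.0,
            noise_sd=0.5, seed=2)
        score = em.values.loc[truth.planted_response_signature].mean(axis=0)
        assert abs(np.corrcoef(score, lfc)[0, 1]) < 0.2

    def test_seed_determinism(self, panel):
        em, _dep, truth = panel
        a = synthdata.generate_drug_response(em, truth.planted_response_signature,
                                             seed=9)
        b = synthdata.generate_drug_response(em, truth.planted_response_signature,
                                             seed=9)
        assert a.equals(b)

    def test_empty_signature_rejected(self, panel):
        em, _dep, _t = panel
        with pytest.raises(InvalidParameterError):
            synthdata.generate_drug_response(em, [])


class TestAnnotations:
    def test_membership_fractions_near_requested(self):
        genes = [f"G{i:04d}" for i in range(2000)]
        tables = synthdata.generate_annotations(
            genes, frac_surface=0.2, frac_secreted=0.15, frac_druggable=0.1,
            seed=1)
        assert len(tables.surfaceome) / 2000 == pytest.approx(0.2, abs=0.05)
        secreted = tables.secretome[
            (tables.secretome["metaz_tag"] != "none")
            | (tables.secretome["hpa_location"] == "Secreted")]
        assert len(secreted) / 2000 == pytest.approx(0.15, abs=0.05)
        assert tables.drug_targets["gene"].nunique() / 2000 == pytest.approx(
            0.1, abs=0.05)

    def test_vocabularies_are_restricted(self):
        genes = [f"G{i:03d}" for i in range(500)]
        tables = synthdata.generate_annotations(genes, seed=2)
        assert set(tables.surfaceome["category"]) <= {1, 2, 3}
        assert set(tables.secretome["metaz_tag"]) <= set(
            synthdata.SECRETED_TAGS) | {"none"}
        assert set(tables.secretome["hpa_location"]) <= {"Secreted", ""}

    def test_every_member_has_some_secretion_evidence(self):
        genes = [f"G{i:03d}" for i in range(500)]
        tables = synthdata.generate_annotations(genes, frac_secreted=0.3, seed=3)
        member = (tables.secretome["metaz_tag"] != "none") | (
            tables.secretome["hpa_location"] == "Secreted")
        # no half-generated rows: membership implies at least one evidence
        assert member.sum() > 0

    def test_zero_fraction_gives_empty_table(self):
        tables = synthdata.generate_annotations(["a", "b", "c"], frac_surface=0.0,
                                                seed=4)
        assert len(tables.surfaceome) == 0


class TestGeneSets:
    def test_planted_sets_drawn_from_pool(self):
        genes = [f"G{i:04d}" for i in range(1000)]
        pool = genes[:100]
        coll, planted = synthdata.generate_gene_sets(
            genes, n_sets=10, set_size_range=(10, 30), n_planted=2, seed=5,
            planted_pool=pool)
        assert len(planted) == 2
        for sid in planted:
            assert set(coll.members(sid)) <= set(pool)

    def test_all_members_inside_universe(self):
        genes = [f"G{i:03d}" for i in range(200)]
        coll, _ = synthdata.generate_gene_sets(genes, n_sets=8,
                                               set_size_range=(5, 20), seed=6)
        for sid in coll:
            assert set(coll.members(sid)) <= set(genes)
            assert len(coll.members(sid)) == len(set(coll.members(sid)))

    def test_empty_collection(self):
        coll, planted = synthdata.generate_gene_sets(
            ["a", "b", "c"], n_sets=0, set_size_range=(1, 2), n_planted=0, seed=7)
        assert len(coll) == 0 and planted == []
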