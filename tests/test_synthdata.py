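"""Generator correctness: seeded determinism, planted-signal structure,
confounding dial, and closed-form moment checks."""

import numpy as np
import pytest

from cads import synthdata
from cads.synthdata import (SMILES_POOL, generate_drugs, generate_labels,
                            generate_profiles, generating_params, plant_truth,
                            signal, simulate)


def profiles_matrix(profiles, layer=0):
    return np.stack([p.C[layer] for p in profiles])


class TestProfiles:
    def test_seeded_determinism_bit_for_bit(self):
        a = generate_profiles(3, 5, 1, seed=7)
        b = generate_profiles(3, 5, 1, seed=7)
        for pa, pb in zip(a, b):
            assert pa.cell_id == pb.cell_id
            assert pa.C.tobytes() == pb.C.tobytes()

    @pytest.mark.parametrize("bad", [(0, 5, 1), (3, 0, 1), (3, 5, 0), (3, 1, 1)])
    def test_degenerate_dimensions_rejected(self, bad):
        with pytest.raises(ValueError):
            generate_profiles(*bad, seed=1)

    def test_per_gene_mean_matches_generating_location(self):
        # Monte-Carlo check against the stated per-gene distribution
        profs = generate_profiles(200, 500, 2, seed=1)
        mu, sigma = generating_params(500, 1)
        X = profiles_matrix(profs)
        se = sigma / np.sqrt(200)
        assert (np.abs(X.mean(axis=0) - mu) < 4 * se).mean() > 0.99

    def test_extra_omics_layers_correlate_with_layer1(self):
        profs = generate_profiles(400, 50, 2, seed=3)
        x1 = profiles_matrix(profs, 0)
        x2 = profiles_matrix(profs, 1)
        corrs = [np.corrcoef(x1[:, g], x2[:, g])[0, 1] for g in range(50)]
        assert abs(np.mean(corrs) - 0.7) < 0.05


class TestTruth:
    def test_seeded_determinism(self):
        a = plant_truth(50, 10, 5, seed=3)
        b = plant_truth(50, 10, 5, seed=3)
        assert a.causal_genes == b.causal_genes
        assert a.gene_effects == b.gene_effects

    def test_causal_and_decoys_disjoint(self):
        t = plant_truth(40, 20, 5, seed=2)
        assert not set(t.causal_genes) & set(t.decoy_genes)
        assert len(t.causal_genes) == len(t.decoy_genes) == 20

    def test_k_exceeding_half_panel_rejected(self):
        with pytest.raises(ValueError):
            plant_truth(40, 21, 5, seed=0)

    def test_zero_causal_genes_allowed(self):
        t = plant_truth(40, 0, 5, seed=0)
        assert t.causal_genes == () and t.gene_effects == {}

    def test_weights_bounded_away_from_zero(self):
        t = plant_truth(100, 30, 5, seed=5)
        mags = np.abs(list(t.gene_effects.values()))
        assert mags.min() >= 0.5 and mags.max() <= 1.5


class TestConfounding:
    @pytest.mark.parametrize("rho", [0.0, 0.6])
    def test_decoy_correlation_tracks_dial(self, rho):
        truth = plant_truth(60, 10, 5, confound_rho=rho, seed=4)
        profs = generate_profiles(1000, 60, 1, seed=9, truth=truth)
        X = profiles_matrix(profs)
        rs = np.array([np.corrcoef(X[:, c], X[:, d])[0, 1]
                       for c, d in zip(truth.causal_genes, truth.decoy_genes)])
        if rho == 0.0:
            assert np.abs(rs).max() < 0.1
        else:
            assert abs(rs.mean() - rho) < 0.05      # dial tracked on average
            assert np.abs(rs - rho).max() < 0.1     # no pair far off


class TestLabels:
    def test_noise_free_labels_exactly_linear_in_causal_features(self):
        ds = simulate(n_cells=20, n_genes=40, k_causal=5, n_drugs=6,
                      n_examples=400, noise_sd=0.0, confound_rho=0.0, seed=5)
        t, prof = ds.truth, {p.cell_id: p for p in ds.profiles}
        feats = []
        for e in ds.examples:
            x = prof[e.cell_id].C.mean(axis=0)
            s = t.drug_latents[e.drug_a_id] @ t.drug_latents[e.drug_b_id]
            feats.append([x[g] * s for g in t.causal_genes])
        y = np.array([e.y for e in ds.examples])
        coef, res, *_ = np.linalg.lstsq(
            np.column_stack([feats, np.ones(len(y))]), y, rcond=None)
        pred = np.column_stack([feats, np.ones(len(y))]) @ coef
        r2 = 1 - ((y - pred) ** 2).sum() / ((y - y.mean()) ** 2).sum()
        assert r2 > 1 - 1e-8

    def test_no_signal_when_no_causal_genes(self):
        # with k=0 the labels are pure noise: the oracle regression on all
        # genes x interaction terms cannot beat chance out of sample
        ds = simulate(n_cells=30, n_genes=20, k_causal=0, n_drugs=10,
                      n_examples=5000, noise_sd=1.0, seed=6)
        prof = {p.cell_id: p for p in ds.profiles}
        t = ds.truth
        X = np.array([
            prof[e.cell_id].C.mean(axis=0)
            * (t.drug_latents[e.drug_a_id] @ t.drug_latents[e.drug_b_id])
            for e in ds.examples])
        y = np.array([e.y for e in ds.examples])
        ntr = 2500
        coef, *_ = np.linalg.lstsq(X[:ntr], y[:ntr], rcond=None)
        pred = X[ntr:] @ coef
        r2 = 1 - ((y[ntr:] - pred) ** 2).sum() / ((y[ntr:] - y[ntr:].mean()) ** 2).sum()
        assert r2 <= 0.05

    def test_variance_matches_closed_form(self):
        # Var(y_raw) = E[s^2] (m^2 + v) + noise^2 with s the latent dot
        # product, m = sum w_g mu_g, v = sum w_g^2 sigma_g^2
        ds = simulate(n_cells=300, n_genes=60, k_causal=12, n_drugs=150,
                      n_examples=20000, noise_sd=0.5, confound_rho=0.0,
                      d_lat=8, seed=7)
        t = ds.truth
        genes = list(t.gene_effects)
        w = np.array([t.gene_effects[g] for g in genes])
        mu = ds.gene_loc[genes]
        sigma = ds.gene_scale[genes]
        m = float(w @ mu)
        v = float((w**2 * sigma**2).sum())
        analytic = 8 * (m**2 + v) + t.noise_sd**2
        raw = ds.standardization.invert(np.array([e.y for e in ds.examples]))
        assert abs(raw.var() / analytic - 1) < 0.10

    def test_labels_standardized(self):
        ds = simulate(n_cells=10, n_genes=20, k_causal=4, n_drugs=6,
                      n_examples=500, seed=8)
        y = np.array([e.y for e in ds.examples])
        assert abs(y.mean()) < 1e-9 and abs(y.std() - 1) < 1e-9

    def test_n_examples_must_be_positive(self):
        ds = simulate(n_cells=5, n_genes=10, k_causal=2, n_drugs=4,
                      n_examples=10, seed=1)
        with pytest.raises(ValueError):
            generate_labels(ds.profiles, ds.drugs, ds.truth, 0, seed=1)


class TestInvariants:
    def test_same_seed_reproduces_dataset_exactly(self):
        a = simulate(n_cells=8, n_genes=16, k_causal=3, n_drugs=5,
                     n_examples=50, seed=13)
        b = simulate(n_cells=8, n_genes=16, k_causal=3, n_drugs=5,
                     n_examples=50, seed=13)
        assert [e.y for e in a.examples] == [e.y for e in b.examples]
        assert a.truth.causal_genes == b.truth.causal_genes
        for pa, pb in zip(a.profiles, b.profiles):
            assert pa.C.tobytes() == pb.C.tobytes()

    def test_signal_depends_only_on_causal_genes(self, rng):
        ds = simulate(n_cells=6, n_genes=20, k_causal=4, n_drugs=4,
                      n_examples=10, noise_sd=0.0, seed=3)
        p = ds.profiles[0]
        base = signal(ds.truth, p, "drug001", "drug002")
        noncausal = [g for g in range(20) if g not in ds.truth.causal_genes]
        C2 = p.C.copy()
        C2[:, noncausal] = C2[:, rng.permutation(noncausal)]
        shuffled = synthdata.CellProfile(p.cell_id, C2, p.gene_ids)
        assert signal(ds.truth, shuffled, "drug001", "drug002") == pytest.approx(base)
        g0 = ds.truth.causal_genes[0]
        C3 = p.C.copy()
        C3[:, g0] += 1.0
        bumped = synthdata.CellProfile(p.cell_id, C3, p.gene_ids)
        assert signal(ds.truth, bumped, "drug001", "drug002") != pytest.approx(base)

    def test_pair_interaction_symmetric(self):
        ds = simulate(n_cells=5, n_genes=10, k_causal=2, n_drugs=5,
                      n_examples=10, seed=9)
        p = ds.profiles[0]
        assert signal(ds.truth, p, "drug001", "drug003") == pytest.approx(
            signal(ds.truth, p, "drug003", "drug001"))

    def test_drug_smiles_distinct_and_valid(self):
        from rdkit import Chem

        drugs = generate_drugs(30, seed=2)
        smiles = [d.smiles for d in drugs]
        assert len(set(smiles)) == 30
        assert all(Chem.MolFromSmiles(s) is not None for s in SMILES_POOL)
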