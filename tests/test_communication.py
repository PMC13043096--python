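"""Ligand-receptor edge scoring, differentials, family aggregation and
per-cell pathway modules."""

import numpy as np
import pandas as pd
import pytest

import thregulon as tg
from thregulon import communication as comm

from conftest import make_adata


def lr_net(rows):
    return pd.DataFrame(rows, columns=["ligand", "receptor", "family"])


def toy_adata():
    """4 cells in 2 populations x 2 conditions at one timepoint; X set
    directly so group means are hand-computable."""
    genes = ["lig", "rec", "other"]
    X = np.array([
        [2.0, 1.0, 0.0],   # A / CTRL
        [2.0, 3.0, 0.0],   # A / CTRL
        [4.0, 4.0, 0.0],   # B / CTRL
        [0.0, 4.0, 0.0],   # B / CTRL
        [6.0, 1.0, 0.0],   # A / HYPO
        [0.0, 5.0, 0.0],   # B / HYPO
    ])
    counts = (X > 0).astype(int)
    adata = make_adata(X, genes=genes, counts=counts)
    adata.obs["population"] = ["A", "A", "B", "B", "A", "B"]
    adata.obs["condition"] = ["CTRL"] * 4 + ["HYPO"] * 2
    adata.obs["timepoint_dpi"] = 0.0
    return adata


class TestFilterExpressed:
    def _detection_adata(self, fracs, n_cells=50):
        """One population; gene i detected in round(frac*n) cells."""
        genes = [f"G{i}" for i in range(len(fracs))] + ["rec"]
        counts = np.zeros((n_cells, len(genes)), dtype=int)
        for i, f in enumerate(fracs):
            counts[: int(round(f * n_cells)), i] = 1
        counts[:, -1] = 1
        adata = make_adata(counts.astype(float), genes=genes, counts=counts)
        adata.obs["population"] = "A"
        return adata

    def test_toy_detection_fractions(self):
        adata = self._detection_adata([0.10, 0.04, 0.06, 0.00])
        net = lr_net([(f"G{i}", "rec", "other") for i in range(4)])
        kept = tg.filter_expressed(net, adata, min_frac=0.05)
        assert sorted(kept["ligand"]) == ["G0", "G2"]

    def test_undetected_ligand_removed_and_vacuous_filter(self):
        adata = self._detection_adata([0.5, 0.0])
        net = lr_net([("G0", "rec", "other"), ("G1", "rec", "other")])
        kept = tg.filter_expressed(net, adata, min_frac=0.05)
        assert list(kept["ligand"]) == ["G0"]
        assert len(tg.filter_expressed(net, adata, min_frac=0.0)) == 2

    def test_empty_network_is_error(self):
        adata = self._detection_adata([0.0])
        net = lr_net([("G0", "rec", "other")])
        with pytest.raises(ValueError, match="empty"):
            tg.filter_expressed(net, adata, min_frac=0.05)


class TestScoreEdges:
    def test_mean_formula_and_directionality(self):
        adata = toy_adata()
        net = lr_net([("lig", "rec", "IL-6")])
        edges = tg.score_edges(adata, net)
        # sender A mean lig (CTRL) = 2.0, receiver B mean rec (CTRL) = 4.0
        ab = edges.query("sender=='A' and receiver=='B' and condition=='CTRL'")
        assert ab["score"].iloc[0] == pytest.approx(0.5 * (2.0 + 4.0))
        ba = edges.query("sender=='B' and receiver=='A' and condition=='CTRL'")
        assert ba["score"].iloc[0] == pytest.approx(0.5 * (2.0 + 2.0))
        aa = edges.query("sender=='A' and receiver=='A' and condition=='CTRL'")
        assert len(aa) == 1  # self edges scored too

    def test_absent_ligand_gives_half_receptor_mean(self):
        adata = toy_adata()
        net = lr_net([("missing", "rec", "IL-6")])
        edges = tg.score_edges(adata, net)
        ab = edges.query("sender=='A' and receiver=='B' and condition=='CTRL'")
        assert ab["score"].iloc[0] == pytest.approx(0.5 * 4.0)

    def test_product_variant_and_linearity(self):
        adata = toy_adata()
        net = lr_net([("lig", "rec", "IL-6")])
        prod = tg.score_edges(adata, net, variant="product")
        ab = prod.query("sender=='A' and receiver=='B' and condition=='CTRL'")
        assert ab["score"].iloc[0] == pytest.approx(2.0 * 4.0)
        doubled = adata.copy()
        doubled.X = adata.X * 2
        e1 = tg.score_edges(adata, net)["score"].to_numpy()
        e2 = tg.score_edges(doubled, net)["score"].to_numpy()
        np.testing.assert_allclose(e2, 2 * e1)


class TestDifferentialEdges:
    def _table(self):
        rows = []
        for cond, score in (("CTRL", 1.5), ("HYPO", 3.0)):
            rows.append({"sender": "A", "receiver": "B", "ligand": "l", "receptor": "r",
                         "family": "IL-6", "condition": cond, "timepoint_dpi": 0.0,
                         "score": score})
        return pd.DataFrame(rows)

    def test_delta_value_and_zero(self):
        diff = tg.differential_edges(self._table())
        assert diff["delta"].iloc[0] == pytest.approx(1.5)
        t = self._table()
        t.loc[t.condition == "HYPO", "score"] = 1.5
        assert tg.differential_edges(t)["delta"].iloc[0] == 0.0

    def test_condition_swap_negates_delta(self):
        t = self._table()
        fwd = tg.differential_edges(t, contrast_levels=("CTRL", "HYPO"))
        rev = tg.differential_edges(t, contrast_levels=("HYPO", "CTRL"))
        np.testing.assert_allclose(fwd["delta"].to_numpy(), -rev["delta"].to_numpy())

    def test_unmatched_rows_dropped(self):
        t = self._table().iloc[:1]
        with pytest.raises(ValueError):
            tg.differential_edges(t)  # HYPO entirely absent
        t2 = pd.concat([self._table(), self._table().assign(ligand="l2").iloc[:1]])
        diff = tg.differential_edges(t2)
        assert len(diff) == 1  # l2 scored only in CTRL -> dropped


class TestAggregatePathways:
    def _diff(self, deltas, family="IL-6"):
        rows = []
        for i, d in enumerate(deltas):
            rows.append({"sender": "A", "receiver": "B", "ligand": f"l{i}", "receptor": f"r{i}",
                         "family": family, "timepoint_dpi": 0.0,
                         "score_ref": 1.0, "score_alt": 1.0 + d, "delta": d})
        return pd.DataFrame(rows)

    def test_mean_delta_and_p_of_null(self):
        out = tg.aggregate_pathways(self._diff([1.0, -1.0, 0.0]))
        assert out["mean_delta"].iloc[0] == pytest.approx(0.0)
        out0 = tg.aggregate_pathways(self._diff([0.0] * 5))
        assert out0["p"].iloc[0] == pytest.approx(1.0)

    def test_small_families_reported_without_p(self):
        out = tg.aggregate_pathways(self._diff([0.5, 0.6]))
        assert len(out) == 1 and np.isnan(out["p"].iloc[0])
        assert out["n_edges"].iloc[0] == 2


class TestPerCellPathwayScore:
    def test_one_and_two_gene_families(self):
        X = np.array([[1.0, 3.0, 7.0], [0.0, 0.0, 2.0]])
        adata = make_adata(X, genes=["l1", "r1", "z"])
        adata.obs["population"] = ["A", "A"]
        net = lr_net([("l1", "r1", "IL-6"), ("z", "z", "IGF-1")])
        two = tg.per_cell_pathway_score(adata, net, "IL-6")
        np.testing.assert_allclose(two.to_numpy(), [2.0, 0.0])  # mean of (1,3); all-zero cell -> 0
        one = tg.per_cell_pathway_score(adata, net, "IGF-1")
        np.testing.assert_allclose(one.to_numpy(), X[:, 2])

    def test_zscored_within_population(self):
        rng = np.random.default_rng(4)
        X = rng.uniform(1, 5, size=(40, 2))
        adata = make_adata(X, genes=["l1", "r1"])
        adata.obs["population"] = ["A"] * 20 + ["B"] * 20
        net = lr_net([("l1", "r1", "IL-6")])
        z = tg.per_cell_pathway_score(adata, net, "IL-6", standardize_by=adata.obs["population"])
        for pop in ("A", "B"):
            sub = z[adata.obs["population"] == pop]
            assert abs(sub.mean()) < 1e-9
            assert sub.std(ddof=1) == pytest.approx(1.0, abs=0.05)

    def test_missing_family_errors(self):
        adata = make_adata(np.ones((2, 2)), genes=["a", "b"])
        net = lr_net([("a", "b", "IL-6")])
        with pytest.raises(KeyError):
            tg.per_cell_pathway_score(adata, net, "Notch/Jagged")


def test_planted_asymmetric_signal_is_directional():
    """Ligand up in FAP senders only: |delta| larger for FAP->X than X->FAP."""
    spec = tg.LRSpec("LigA", "RecA", "FAP", "myogenic", "IGF-1",
                     strength={("HYPO", 0.0): 1.0})
    cfg = tg.SimConfig(populations=("FAP", "myogenic", "myeloid"), timepoints=(0,),
                       cells_per_stratum=100, n_genes=400, tf_specs=[], lr_specs=[spec],
                       n_background_lr_pairs=0, qc_fail_fraction=0.0, seed=6)
    study = tg.generate_study(cfg)
    adata = tg.normalize_log2cpm(study.adata)
    diff = tg.differential_edges(tg.score_edges(adata, study.lr_network))
    d = diff.set_index(["sender", "receiver"])["delta"].abs()
    for other in ("myogenic", "myeloid"):
        assert d.loc[("FAP", other)] > d.loc[(other, "FAP")]
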