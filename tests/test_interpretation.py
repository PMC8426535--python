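"""Attention-interpretation tests: profiles, group alignments, shuffle
control, ratios, and segment extraction."""

import numpy as np
import pytest

from subloc.encoding import EncodedProtein, ProteinRecord
from subloc.interpretation import (
    AttentionProfile,
    attention_ratio,
    cleavage_profile,
    extract_segments,
    protein_attention,
    shuffle_control,
    terminus_profile,
    write_logo_matrix,
    write_profile_tsv,
    write_segments_fasta,
)
from subloc.network import Model, ModelConfig
from subloc.training import EnsembleModel


class _StubModel:
    """Model stand-in returning a fixed attention matrix (synthetic)."""

    def __init__(self, A, n_org=2):
        self.A = A
        self.cfg = ModelConfig(n_organelles=n_org, encode_length=A.shape[1],
                               hidden_total=8, heads=A.shape[0], attn_inner=6)

    def predict(self, feats, mask):
        from subloc.network import ScoreMatrix

        return [ScoreMatrix.from_sub(np.full((8, 2), 0.5))], self.A[None]


def _enc(length, valid, origin=None):
    feats = np.zeros((length, 25))
    mask = np.zeros(length, dtype=np.uint8)
    mask[:valid] = 1
    if origin is None:
        origin = np.concatenate(
            [np.arange(1, valid + 1), np.zeros(length - valid, dtype=int)]
        )
    return EncodedProtein(feats, mask, origin, valid)


def _profile(weights, raw_length=None):
    weights = np.asarray(weights, dtype=float)
    return AttentionProfile(
        positions=np.arange(1, len(weights) + 1),
        weights=weights,
        raw_length=raw_length or len(weights),
    )


class TestProteinAttention:
    def test_uniform_heads_give_flat_profile(self):
        A = np.zeros((3, 120))
        A[:, :100] = 1.0 / 100
        prof = protein_attention(_StubModel(A), _enc(120, 100))
        assert prof.positions.shape == (100,)
        np.testing.assert_allclose(prof.weights, 0.01)

    def test_single_head_peak_maps_to_raw_position(self):
        A = np.zeros((1, 50))
        A[0, 6] = 1.0  # encoded position 7
        prof = protein_attention(_StubModel(A), _enc(50, 30))
        assert prof.positions[np.argmax(prof.weights)] == 7

    def test_head_average_conserves_unit_mass(self, rng):
        cfg = ModelConfig(n_organelles=3, encode_length=40, hidden_total=8,
                          heads=3, attn_inner=6)
        model = Model(cfg)
        x = _enc(40, 33)
        x.features[:33] = rng.normal(size=(33, 25))
        prof = protein_attention(model, x)
        assert prof.weights.sum() == pytest.approx(1.0, abs=1e-6)
        assert (prof.weights >= 0).all()

    def test_truncated_protein_reports_raw_coordinates(self):
        origin = np.concatenate([np.arange(1, 26), np.arange(76, 101)])
        A = np.zeros((1, 50))
        A[0, -1] = 1.0
        prof = protein_attention(_StubModel(A), _enc(50, 50, origin=origin))
        assert prof.positions[np.argmax(prof.weights)] == 100
        assert prof.gap == (26, 75)

    def test_fully_encoded_protein_has_no_gap(self):
        A = np.full((1, 30), 1.0 / 30)
        prof = protein_attention(_StubModel(A), _enc(30, 30))
        assert prof.gap is None


class TestGroupProfiles:
    def test_identical_profiles_average_to_themselves(self):
        p = _profile([0.1, 0.2, 0.3, 0.4])
        g = terminus_profile([p, p], ["MKVL", "MKVL"], end="N", span=4)
        np.testing.assert_allclose(g.mean_attention, p.weights)
        assert g.frequencies[0, 12] == 1.0  # column M

    def test_position_mean_of_two_proteins(self):
        a = _profile([0.2, 0.1])
        b = _profile([0.4, 0.3])
        g = terminus_profile([a, b], ["MK", "MV"], end="N", span=2)
        assert g.mean_attention[0] == pytest.approx(0.3)

    def test_c_terminal_alignment_counts_from_the_end(self):
        a = _profile([0.0, 0.0, 0.9])
        g = terminus_profile([a], ["MKW"], end="C", span=2)
        assert list(g.offsets) == [1, 2]
        assert g.mean_attention[0] == pytest.approx(0.9)  # last residue

    def test_group_vs_loop_oracle(self, rng):
        profiles, seqs = [], []
        for _ in range(50):
            L = int(rng.integers(20, 60))
            w = rng.random(L)
            profiles.append(_profile(w / w.sum()))
            seqs.append("".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), L)))
        g = terminus_profile(profiles, seqs, end="N", span=15)
        for pos in range(1, 16):
            vals = [p.weights[pos - 1] for p in profiles
                    if p.raw_length >= pos]
            assert g.mean_attention[pos - 1] == pytest.approx(np.mean(vals))


class TestCleavageProfile:
    def _rec(self, seq, site):
        return ProteinRecord(accession="P", sequence=seq, cleavage_site=site)

    def test_window_around_site(self):
        seq = "M" * 40
        prof = _profile(np.linspace(0, 1, 40))
        g = cleavage_profile([prof], [self._rec(seq, 25)], before=10, after=10)
        assert list(g.offsets) == list(range(-10, 11))
        assert g.counts.sum() == 21

    def test_leading_positions_missing_for_early_site(self):
        seq = "M" * 30
        prof = _profile(np.ones(30) / 30)
        g = cleavage_profile([prof], [self._rec(seq, 5)], before=10, after=10)
        assert list(g.offsets) == list(range(-4, 11))

    def test_records_without_site_warn_and_skip(self):
        prof = _profile(np.ones(20) / 20)
        with_site = self._rec("M" * 20, 10)
        without = ProteinRecord(accession="Q", sequence="M" * 20)
        with pytest.warns(UserWarning, match="without cleavage site"):
            g = cleavage_profile([prof, prof], [with_site, without],
                                 before=5, after=5)
        assert g.counts.max() == 1


class TestShuffleControl:
    def _tiny_ens(self):
        cfg = ModelConfig(n_organelles=2, encode_length=40, hidden_total=8,
                          heads=2, attn_inner=6)
        from subloc.hierarchy import LabelHierarchy

        h = LabelHierarchy(
            organelles=["a", "b"],
            grid=[["s1", "s2"]] + [[None, None]] * 7,
            name_to_cell={"s1": (0, 0), "s2": (0, 1)},
        )
        return EnsembleModel(models=[Model(cfg)], hierarchy=h)

    def test_same_seed_identical_group_profile(self, rng):
        recs = [
            ProteinRecord(accession=f"P{i}",
                          sequence="".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 35)))
            for i in range(4)
        ]
        ens = self._tiny_ens()
        a = shuffle_control(ens, recs, seed=11, span=20)
        b = shuffle_control(ens, recs, seed=11, span=20)
        np.testing.assert_array_equal(a.mean_attention, b.mean_attention)
        np.testing.assert_array_equal(a.frequencies, b.frequencies)

    def test_shuffle_preserves_composition(self, rng):
        # the permutation behind shuffle_control is composition-preserving:
        # group residue frequencies summed over positions match the originals
        recs = [ProteinRecord(accession="P0", sequence="MKKKLLLVVA")]
        ens = self._tiny_ens()
        g = shuffle_control(ens, recs, seed=3, span=10)
        total = g.frequencies.sum(axis=0)
        from subloc.encoding import AA_ORDER

        expected = {aa: recs[0].sequence.count(aa) for aa in set(recs[0].sequence)}
        for aa, n in expected.items():
            assert total[AA_ORDER.index(aa)] == pytest.approx(n)


class TestAttentionRatio:
    def _group(self, vals, anchor="N"):
        from subloc.interpretation import GroupProfile

        vals = np.asarray(vals, dtype=float)
        return GroupProfile(
            anchor=anchor, offsets=np.arange(1, len(vals) + 1),
            mean_attention=vals, counts=np.ones(len(vals)),
            frequencies=np.zeros((len(vals), 20)),
        )

    def test_identical_profiles_give_unit_ratio(self):
        g = self._group([0.1, 0.2, 0.3])
        _, ratio = attention_ratio(g, g)
        np.testing.assert_allclose(ratio, 1.0)

    def test_elementwise_division(self):
        _, ratio = attention_ratio(self._group([0.02]), self._group([0.01]))
        assert ratio[0] == pytest.approx(2.0)

    def test_floor_flags_instead_of_dividing(self):
        _, ratio = attention_ratio(
            self._group([0.5, 0.5]), self._group([0.25, 1e-9])
        )
        assert ratio[0] == pytest.approx(2.0)
        assert np.isnan(ratio[1])

    def test_anchor_mismatch_rejected(self):
        with pytest.raises(ValueError, match="anchor"):
            attention_ratio(self._group([1.0]), self._group([1.0], anchor="C"))


class TestExtractSegments:
    def test_single_peak_window(self):
        w = np.zeros(30)
        w[14] = 1.0  # residue 15
        seq = "ACDEFGHIKLMNPQRSTVWY" + "ACDEFGHIKL"
        seg, coords = extract_segments(_profile(w), seq, top_k=1, flank=10)
        assert coords == [(5, 25)]
        assert seg == seq[4:25]
        assert len(seg) == 21

    def test_peak_near_start_is_clipped(self):
        w = np.zeros(30)
        w[2] = 1.0
        seg, coords = extract_segments(_profile(w), "M" * 30, top_k=1, flank=10)
        assert coords == [(1, 13)]

    def test_overlapping_windows_merge(self):
        w = np.zeros(40)
        w[14] = 1.0
        w[19] = 0.9
        seg, coords = extract_segments(_profile(w), "A" * 40, top_k=2, flank=10)
        assert coords == [(5, 30)]
        assert "X" not in seg

    def test_disjoint_windows_joined_by_spacer(self):
        w = np.zeros(80)
        w[4] = 1.0
        w[59] = 0.9
        seq = "".join("ACDEFGHIKL"[i % 10] for i in range(80))
        seg, coords = extract_segments(_profile(w), seq, top_k=2, flank=10)
        assert coords == [(1, 15), (50, 70)]
        assert seg == seq[0:15] + "X" * 10 + seq[49:70]

    def test_ties_resolved_toward_smaller_index(self):
        w = np.zeros(60)
        w[9] = w[49] = 1.0
        _, coords = extract_segments(_profile(w), "A" * 60, top_k=1, flank=5)
        assert coords == [(5, 15)]

    def test_despacered_output_reconstructs_substrings(self, rng):
        for _ in range(20):
            L = int(rng.integers(30, 90))
            seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), L))
            w = rng.random(L)
            seg, _ = extract_segments(_profile(w), seq, top_k=3, flank=6)
            for piece in seg.split("X" * 6):
                if piece:
                    assert piece.replace("X", "") in seq or piece in seq


class TestTrainedModelProperties:
    """Interpretation behavior of the trained reduced-scale recovery model."""

    def test_attention_drops_after_cleavage_site(self, recovery):
        """Group attention aligned at the cleavage site falls off sharply
        right after the site for the signal-peptide class."""
        test_recs = recovery["test_recs"]
        idx = {r.accession: i for i, r in enumerate(recovery["records"])}
        sig = [r for r in test_recs
               if "mitochondrial matrix" in r.suborganelle_labels]
        profs = [
            protein_attention(recovery["ens"],
                              recovery["samples"][idx[r.accession]].x)
            for r in sig
        ]
        g = cleavage_profile(profs, sig, before=10, after=10)
        pre = np.nanmean(g.mean_attention[(g.offsets >= -10) & (g.offsets <= 0)])
        post = np.nanmean(g.mean_attention[(g.offsets >= 1) & (g.offsets <= 10)])
        assert pre > post

    def test_shuffling_removes_motif_interior_enrichment(self, recovery):
        """After residue shuffling, former motif positions of the internal
        basic-stretch class attract no more attention than the rest of the
        interior (two-sided sign-flip permutation test, p > 0.05)."""
        from subloc.encoding import blosum_fallback, encode, load_physchem

        nls_t = {t.accession: t for t in recovery["truths"]
                 if t.class_name == "internal_nls"}
        nls = [r for r in recovery["test_recs"] if r.accession in nls_t]
        pc = load_physchem()
        prng = np.random.default_rng(56)
        diffs = []
        for rec in nls:
            perm = prng.permutation(len(rec.sequence))
            shuffled = "".join(rec.sequence[i] for i in perm)
            x = encode(shuffled, blosum_fallback(shuffled), pc,
                       encode_length=200)
            prof = protein_attention(recovery["ens"], x)
            t = nls_t[rec.accession]
            interior = (prof.positions >= 16) & (
                prof.positions <= len(rec.sequence) - 15
            )
            w = prof.weights[interior]
            pos = prof.positions[interior]
            in_motif = (pos >= t.start) & (pos <= t.end)
            if in_motif.any() and (~in_motif).any():
                diffs.append(w[in_motif].mean() - w[~in_motif].mean())
        diffs = np.array(diffs)
        stat = abs(diffs.mean())
        flips = prng.random((5000, diffs.size)) < 0.5
        null = (np.where(flips, -1.0, 1.0) * diffs).mean(axis=1)
        p = float((np.abs(null) >= stat).mean())
        assert p > 0.05, p


def test_exports_write_parseable_files(tmp_path):
    from subloc.interpretation import GroupProfile

    g = GroupProfile(
        anchor="N", offsets=np.array([1, 2]),
        mean_attention=np.array([0.5, np.nan]), counts=np.array([2, 0]),
        frequencies=np.zeros((2, 20)),
    )
    write_profile_tsv(g, tmp_path / "p.tsv")
    lines = (tmp_path / "p.tsv").read_text().splitlines()
    assert len(lines) == 3 and "NA" in lines[2]
    write_logo_matrix(g, tmp_path / "logo.tsv")
    write_segments_fasta({"P1": "MKVXXL"}, tmp_path / "seg.fasta",
                         hints_path=tmp_path / "glam2.tsv")
    assert (tmp_path / "seg.fasta").read_text().startswith(">P1")
    assert "initial_columns\t15" in (tmp_path / "glam2.tsv").read_text()
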