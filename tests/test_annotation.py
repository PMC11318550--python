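"""PTM / IDR / feature / auxiliary-motif annotation."""

import numpy as np
import pytest

from slimscan import (Dataset, FeatureInterval, ProteinRecord, PtmSite,
                      annotate_auxiliary, annotate_features, annotate_idr,
                      annotate_ptm, compile_motif, filter_without_connections,
                      load_features, load_ptm_dbptm, load_ptm_psp, scan)
from slimscan.motif_engine import MotifMatch


def _match(acc="P1", start=2, end=8, groups=None, spans=None):
    return MotifMatch(accession=acc, motif="m", start=start, end=end,
                      matched="X" * (end - start + 1), groups=groups,
                      group_spans=spans)


class TestPspLoader:
    PSP = ("PhosphoSitePlus synthetic extract\n"
           "\n"
           "licence preamble line\n"
           "GENE\tACC_ID\tMOD_RSD\tAmbiguous_Site\n"
           "G1\tP1\tT5-p\t0\n"
           "G1\tP1\tS9-p\t1\n"
           "G2\tP2\tK7-ub\t0\n"
           "G3\tP3\tbroken\t0\n")

    def test_mod_rsd_decoded(self, tmp_path):
        path = tmp_path / "psp.tsv"
        path.write_text(self.PSP)
        with pytest.warns(UserWarning, match="skipped 1"):
            sites = load_ptm_psp(path)
        by_acc = {s.accession: s for s in sites}
        assert by_acc["P1"].position == 5
        assert by_acc["P1"].residue == "T"
        assert by_acc["P1"].modification == "phosphorylation"
        assert by_acc["P2"].modification == "ubiquitination"

    def test_ambiguous_dropped_by_default(self, tmp_path):
        path = tmp_path / "psp.tsv"
        path.write_text(self.PSP)
        with pytest.warns(UserWarning):
            sites = load_ptm_psp(path)
        assert not any(s.position == 9 for s in sites)
        with pytest.warns(UserWarning):
            kept = load_ptm_psp(path, drop_ambiguous=False)
        assert any(s.position == 9 and s.ambiguous for s in kept)

    def test_modification_filter(self, tmp_path):
        path = tmp_path / "psp.tsv"
        path.write_text(self.PSP)
        with pytest.warns(UserWarning):
            sites = load_ptm_psp(path, modification_filter="Phosphorylation")
        assert {s.modification for s in sites} == {"phosphorylation"}

    def test_missing_accession_column_fatal(self, tmp_path):
        path = tmp_path / "psp.tsv"
        path.write_text("GENE\tMOD_RSD\tAmbiguous_Site\nG1\tT5-p\t0\n")
        with pytest.raises(ValueError, match="ACC_ID"):
            load_ptm_psp(path)


class TestDbptmLoader:
    def _proteome(self):
        return Dataset([ProteinRecord("P1", "MASTAYKLQE")])

    def _write(self, tmp_path, rows):
        path = tmp_path / "dbptm.tsv"
        path.write_text("".join(rows))
        return path

    def test_plausible_site_unflagged(self, tmp_path):
        path = self._write(tmp_path, ["ID1\tP1\t4\tPhosphorylation\tev\n"])
        (site,) = load_ptm_dbptm(path, validate_residue=True,
                                 proteome=self._proteome())
        assert site.residue == "T"
        assert site.flags == ()

    def test_implausible_residue_flagged(self, tmp_path):
        # position 5 is A: phosphorylation there is implausible
        path = self._write(tmp_path, ["ID1\tP1\t5\tPhosphorylation\tev\n"])
        (site,) = load_ptm_dbptm(path, validate_residue=True,
                                 proteome=self._proteome())
        assert "implausible_residue" in site.flags

    def test_out_of_bounds_flagged_and_strict_drops(self, tmp_path):
        path = self._write(tmp_path, ["ID1\tP1\t99\tPhosphorylation\tev\n"])
        (site,) = load_ptm_dbptm(path, validate_residue=True,
                                 proteome=self._proteome())
        assert "out_of_bounds" in site.flags
        assert load_ptm_dbptm(path, validate_residue=True,
                              proteome=self._proteome(), strict=True) == []

    def test_flag_dont_drop_default(self, tmp_path):
        path = self._write(tmp_path, ["ID1\tP1\t5\tPhosphorylation\tev\n"])
        sites = load_ptm_dbptm(path, validate_residue=True,
                               proteome=self._proteome())
        assert len(sites) == 1


class TestAnnotatePtm:
    def test_whole_match_containment_inclusive(self):
        sites = [PtmSite("P1", 5, "S", "phosphorylation"),
                 PtmSite("P1", 2, "T", "phosphorylation"),
                 PtmSite("P1", 8, "S", "phosphorylation"),
                 PtmSite("P1", 20, "S", "phosphorylation")]
        (m,) = annotate_ptm([_match()], sites)
        assert m.annotations["ptm_connected"]
        assert m.annotations["ptm_count"] == 3  # boundaries 2 and 8 included

    def test_group_scope(self):
        spans = tuple((i, i) for i in range(2, 9))
        m = _match(spans=spans)
        sites = [PtmSite("P1", 5, "S", "phosphorylation")]
        annotate_ptm([m], sites, scope=4)   # group 4 spans [5,5]
        assert m.annotations["ptm_connected"]
        annotate_ptm([m], sites, scope=5)   # group 5 spans [6,6]
        assert not m.annotations["ptm_connected"]

    def test_group_scope_out_of_range(self):
        m = _match(spans=((2, 2),))
        with pytest.raises(ValueError, match="out of range"):
            annotate_ptm([m], [], scope=9)

    def test_filter_without_connections(self):
        sites = [PtmSite("P1", 5, "S", "phosphorylation")]
        matches = [_match("P1"), _match("P2"), _match("P3")]
        annotate_ptm(matches, sites)
        kept = filter_without_connections(matches)
        assert [m.accession for m in kept] == ["P1"]

    def test_filter_before_annotation_errors(self):
        with pytest.raises(ValueError, match="annotate_ptm"):
            filter_without_connections([_match()])

    def test_equals_bruteforce_join(self):
        rng = np.random.default_rng(21)
        matches = [_match(f"P{i}", start=int(s), end=int(s) + 6)
                   for i, s in enumerate(rng.integers(1, 50, size=30))]
        sites = [PtmSite(f"P{int(i)}", int(p), "S", "phosphorylation")
                 for i, p in zip(rng.integers(0, 30, size=60),
                                 rng.integers(1, 60, size=60))]
        annotate_ptm(matches, sites)
        kept = {id(m) for m in filter_without_connections(matches)}
        brute = {id(m) for m in matches
                 if any(s.accession == m.accession
                        and m.start <= s.position <= m.end for s in sites)}
        assert kept == brute


class TestIdrAndFeatures:
    def test_partial_overlap_percent(self):
        feats = [FeatureInterval("P1", 5, 20, "Disordered")]
        (m,) = annotate_idr([_match(start=2, end=8)], feats)
        assert m.annotations["idr_overlap_percent"] == pytest.approx(57.1)

    def test_fully_inside_and_no_idr(self):
        feats = [FeatureInterval("P1", 1, 50, "Disordered")]
        (m,) = annotate_idr([_match()], feats)
        assert m.annotations["idr_overlap_percent"] == 100.0
        (m2,) = annotate_idr([_match(acc="P9")], feats)
        assert m2.annotations["idr_overlap_percent"] == 0.0

    def test_merging_overlapping_idrs_invariant(self):
        split = [FeatureInterval("P1", 3, 6, "Disordered"),
                 FeatureInterval("P1", 5, 10, "Disordered")]
        merged = [FeatureInterval("P1", 3, 10, "Disordered")]
        (a,) = annotate_idr([_match()], split)
        (b,) = annotate_idr([_match()], merged)
        assert a.annotations["idr_overlap_percent"] == \
            b.annotations["idr_overlap_percent"]

    def test_features_intersection_sorted_and_boundaries(self):
        feats = [FeatureInterval("P1", 9, 12, "Domain"),     # adjacent: 9 > end 8
                 FeatureInterval("P1", 8, 10, "Region"),
                 FeatureInterval("P1", 1, 3, "Binding site")]
        (m,) = annotate_features([_match(start=2, end=8)], feats)
        hits = m.annotations["features"]
        assert [(f.start, f.type) for f in hits] == [(1, "Binding site"),
                                                     (8, "Region")]

    def test_feature_tsv_round_trip(self, tmp_path):
        from slimscan import write_features
        feats = [FeatureInterval("P1", 3, 9, "Disordered", "idr"),
                 FeatureInterval("P2", 1, 4, "Domain", None)]
        path = tmp_path / "features.tsv"
        write_features(feats, path)
        back = load_features(path)
        assert [(f.accession, f.start, f.end, f.type) for f in back] == \
            [("P1", 3, 9, "Disordered"), ("P2", 1, 4, "Domain")]


class TestAuxiliary:
    def _setup(self):
        ds = Dataset([ProteinRecord("P1", "MAASTLLAKRKRK"),
                      ProteinRecord("P2", "MAASTLLAAAAAA")])
        primary = compile_motif("primary", "ASTLLA")
        aux = compile_motif("aux", "KRKRK")
        return ds, scan(ds, primary), aux

    def test_aux_found_per_protein(self):
        ds, primaries, aux = self._setup()
        annotated = annotate_auxiliary(primaries, ds, aux)
        by_acc = {m.accession: m for m in annotated}
        assert by_acc["P1"].annotations["aux_found"]
        assert not by_acc["P2"].annotations["aux_found"]

    def test_keep_only_aux_filter(self):
        ds, primaries, aux = self._setup()
        kept = annotate_auxiliary(primaries, ds, aux, keep_only_aux=True)
        assert [m.accession for m in kept] == ["P1"]

    def test_threshold_counts_and_best_score(self, kinase_motif,
                                             kinase_sampler):
        from slimscan import train_pssm
        rng = np.random.default_rng(17)
        instances = [kinase_sampler(rng) for _ in range(500)]
        aux = kinase_motif
        aux.pssm = train_pssm(instances, aux)
        # protein carrying one consensus-like (high score) and one weak hit
        strong = instances[0]
        ds = Dataset([ProteinRecord("P1", "M" + strong + "GGGG" + "AADTVYE")])
        primaries = [MotifMatch("P1", "p", 1, 1, "M")]
        annotate_auxiliary(primaries, ds, aux, aux_threshold=50.0)
        ann = primaries[0].annotations
        scores = [m.score for m in
                  __import__("slimscan").score_matches(aux.pssm, scan(ds, aux))]
        n_above = sum(s >= 50 for s in scores)
        assert ann["aux_count"] == n_above
        assert ann["aux_best_score"] == pytest.approx(max(scores))

    def test_threshold_without_pssm_errors(self):
        ds, primaries, aux = self._setup()
        with pytest.raises(ValueError, match="PSSM"):
            annotate_auxiliary(primaries, ds, aux, aux_threshold=50.0)
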