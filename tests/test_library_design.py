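"""Library design: guide discovery, filters, pairing, controls, oligos."""

import re

import numpy as np
import pytest

from crestkit.library_design import (
    CONTROL_FORBIDDEN_MOTIFS,
    OLIGO_TEMPLATES,
    SPACER_FORBIDDEN_MOTIFS,
    ControlPair,
    CoverageUnattainableError,
    DesignConfig,
    GenomeSequence,
    GuideSite,
    OligoAssemblyError,
    PairedGuide,
    TargetWindow,
    assemble_oligo,
    assemble_oligos,
    coverage_profile,
    design_library,
    design_negative_controls,
    design_positive_controls,
    design_to_manifest,
    export_library,
    filter_spacers,
    normalize_and_filter,
    normalize_spacer,
    pair_sequential,
    read_manifest,
    revcomp,
    scan_guide_sites,
)
from crestkit.simulate import make_genome


def _regex_site_count(seq: str) -> int:
    """Independent oracle: count NGG protospacers on both strands by regex."""
    plus = len(re.findall(r"(?=[ACGT]{21}GG)", seq))
    minus = len(re.findall(r"(?=CC[ACGT]{21})", seq))
    return plus + minus


class TestScanGuideSites:
    def test_no_pam_no_sites(self):
        genome = GenomeSequence("g", "ACAT" * 20)
        sites = scan_guide_sites(genome, TargetWindow("g", 0, 80))
        assert sites == []

    def test_single_plus_strand_site(self):
        spacer = "ATCGATCGATCGATCGATCG"
        genome = GenomeSequence("g", spacer + "AGG")
        sites = scan_guide_sites(genome, TargetWindow("g", 0, 23))
        assert len(sites) == 1
        site = sites[0]
        assert site.spacer == spacer
        assert site.strand == "+"
        assert site.pam_start == 20
        assert site.cut_site == 17  # 3 bp 5' of the PAM

    def test_minus_strand_site_geometry(self):
        # forward CCN + 20 nt means an NGG protospacer on the reverse strand
        core = "ATCGATCGATCGATCGATCG"
        genome = GenomeSequence("g", "CCA" + core)
        sites = scan_guide_sites(genome, TargetWindow("g", 0, 23))
        assert len(sites) == 1
        site = sites[0]
        assert site.strand == "-"
        assert site.spacer == revcomp(core)
        assert site.cut_site == 6

    def test_count_matches_regex_oracle(self):
        genome, _ = make_genome(1000, seed=7)
        sites = scan_guide_sites(genome, TargetWindow(genome.name, 0, 1000))
        assert len(sites) == _regex_site_count(genome.sequence)

    def test_sites_sorted_by_cut(self):
        genome, _ = make_genome(2000, seed=8)
        sites = scan_guide_sites(genome, TargetWindow(genome.name, 0, 2000))
        cuts = [s.cut_site for s in sites]
        assert cuts == sorted(cuts)

    def test_window_outside_genome_errors(self):
        genome = GenomeSequence("g", "ACGT" * 100)
        with pytest.raises(ValueError, match="outside genome"):
            scan_guide_sites(genome, TargetWindow("g", 0, 1000))


class TestNormalizeSpacer:
    def test_g_start_unchanged(self):
        spacer = "G" + "ACGT" * 4 + "ACG"
        assert len(spacer) == 20
        assert normalize_spacer(spacer) == spacer

    def test_non_g_start_prepends(self):
        spacer = "ACGTACGTACGTACGTACGT"
        out = normalize_spacer(spacer)
        assert out == "G" + spacer
        assert len(out) == 21

    @pytest.mark.parametrize("bad", ["N" * 20, "ACGT", "ACGTACGTACGTACGTACGU"])
    def test_invalid_input_errors(self, bad):
        with pytest.raises(ValueError):
            normalize_spacer(bad)


def _mk_site(spacer, cut=0):
    return GuideSite(spacer[-20:], spacer, "+", cut + 3, cut)


class TestFilterSpacers:
    @pytest.mark.parametrize("motif", SPACER_FORBIDDEN_MOTIFS)
    def test_each_forbidden_motif_removed(self, motif):
        spacer = ("G" + motif + "ACGTACGTACGTACG")[:20]
        site = _mk_site(spacer)
        assert filter_spacers([site], DesignConfig()) == []

    def test_clean_spacer_retained(self):
        site = _mk_site("GACGTACGTACGTACGTACG")
        assert filter_spacers([site], DesignConfig()) == [site]

    def test_matches_substring_oracle_on_random_spacers(self, rng):
        spacers = ["".join(rng.choice(list("ACGT"), 20)) for _ in range(1000)]
        sites = [_mk_site(s if s.startswith("G") else "G" + s) for s in spacers]
        kept = filter_spacers(sites, DesignConfig())
        oracle = [s for s in sites
                  if not any(m in s.expressed_spacer for m in SPACER_FORBIDDEN_MOTIFS)]
        assert kept == oracle


class TestPairSequential:
    def test_grid_sites_reach_coverage(self):
        # cut sites every 50 bp across 10 kb
        sites = [_mk_site("GACGTACGTACGTACGTACG", cut=c)
                 for c in range(0, 10_000, 50)]
        window = TargetWindow("g", 0, 10_000)
        cfg = DesignConfig(target_coverage=2, deletion_size_window=(1800, 2200))
        pairs = pair_sequential(sites, window, cfg)
        _, summary = coverage_profile(pairs, window)
        assert 2.0 <= summary["mean"] <= 2.5
        mean_len = np.mean([p.deletion_length for p in pairs])
        assert 1800 <= mean_len <= 2200
        # coverage identity oracle: mean * L == sum of deletion lengths
        total = sum(min(p.deletion[1], 10_000) - max(p.deletion[0], 0) for p in pairs)
        assert summary["mean"] * 10_000 == pytest.approx(total)

    def test_single_site_unattainable(self):
        sites = [_mk_site("GACGTACGTACGTACGTACG", cut=100)]
        with pytest.raises(CoverageUnattainableError):
            pair_sequential(sites, TargetWindow("g", 0, 10_000), DesignConfig())

    def test_unattainable_reports_achieved_coverage(self):
        sites = [_mk_site("GACGTACGTACGTACGTACG", cut=c) for c in (0, 2000)]
        try:
            pair_sequential(sites, TargetWindow("g", 0, 100_000),
                            DesignConfig(target_coverage=5))
        except CoverageUnattainableError as e:
            assert 0 <= e.achieved < 5
        else:
            pytest.fail("expected CoverageUnattainableError")

    def test_deterministic(self, small_design):
        again = pair_sequential(small_design["sites"], small_design["window"],
                                small_design["cfg"])
        assert again == small_design["pairs"]

    def test_deletion_lengths_in_window(self, small_design):
        dmin, dmax = small_design["cfg"].deletion_size_window
        for p in small_design["pairs"]:
            if not p.clipped:
                assert dmin <= p.deletion_length <= dmax


class TestCoverageProfile:
    def test_single_interval(self):
        pair = PairedGuide("p", _mk_site("GACGTACGTACGTACGTACG", 0),
                           _mk_site("GACGTACGTACGTACGTACG", 100), "g")
        profile, summary = coverage_profile([pair], TargetWindow("g", 0, 200))
        assert summary["mean"] == pytest.approx(0.5)
        assert summary["max"] == 1

    def test_additivity(self):
        pair = PairedGuide("p", _mk_site("GACGTACGTACGTACGTACG", 0),
                           _mk_site("GACGTACGTACGTACGTACG", 100), "g")
        one, _ = coverage_profile([pair], TargetWindow("g", 0, 200))
        two, _ = coverage_profile([pair, pair], TargetWindow("g", 0, 200))
        assert np.array_equal(two, 2 * one)

    def test_empty_design_zero_profile(self):
        profile, summary = coverage_profile([], TargetWindow("g", 0, 100))
        assert not profile.any()
        assert summary["mean"] == 0

    def test_matches_per_base_oracle(self, small_design):
        window = small_design["window"]
        pairs = small_design["pairs"][:50]
        profile, _ = coverage_profile(pairs, window)
        oracle = np.zeros(len(window), dtype=int)
        for p in pairs:
            a, b = p.deletion
            for pos in range(max(a, 0), min(b, window.end)):
                oracle[pos] += 1
        assert np.array_equal(profile, oracle)


class TestNegativeControls:
    def test_controls_pass_full_rescan_oracle(self):
        genome, _ = make_genome(100_000, seed=33)
        cfg = DesignConfig()
        controls = design_negative_controls(genome, 10, cfg)
        assert len(controls) == 10
        seq = genome.sequence
        both = seq + "#" + revcomp(seq)
        for c in controls:
            for expressed in (c.seq1, c.seq2):
                genomic = expressed[1:] if len(expressed) == 21 else expressed
                # unique across both strands
                assert both.count(genomic) == 1
                # no NGG immediately 3' of the occurrence
                i = seq.find(genomic)
                assert i >= 0
                assert seq[i + 21:i + 23] != "GG"
                # motif-free (TTNTT with N = any base)
                assert not re.search("|".join(
                    m.replace("N", "[ACGT]") for m in CONTROL_FORBIDDEN_MOTIFS
                ), expressed)
                assert expressed.startswith("G")

    def test_insufficient_genome_errors(self):
        genome = GenomeSequence("g", "ACGT" * 30)  # repetitive: nothing unique
        with pytest.raises(ValueError, match="insufficient"):
            design_negative_controls(genome, 5, DesignConfig())


@pytest.fixture(scope="module")
def reporters():
    egfp, _ = make_genome(500, gc=0.6, seed=44, name="EGFP")
    mcherry, _ = make_genome(500, gc=0.6, seed=45, name="mCherry")
    return {"EGFP": egfp.sequence, "mCherry": mcherry.sequence}


class TestPositiveControls:

    def test_five_pairs_per_reporter(self, reporters):
        pairs = design_positive_controls(reporters)
        assert len(pairs) == 10
        assert sum(p.target == "EGFP" for p in pairs) == 5
        assert all(p.kind == "positive" for p in pairs)

    def test_index_pairing_scheme(self, reporters):
        pairs = design_positive_controls(reporters)
        indices = {tuple(int(x) for x in p.id.split("_")[2:]) for p in pairs
                   if p.target == "EGFP"}
        assert indices == {(1, 6), (2, 7), (3, 8), (4, 9), (5, 10)}

    def test_too_few_sites_errors(self):
        with pytest.raises(ValueError, match="need 10"):
            design_positive_controls({"EGFP": "ACGTAGG" + "A" * 40})


class TestAssembleOligo:
    def _pair(self, s1="GACGTACGTACGTACGTACG", s2="GCATGCATGCATGCATGCAT"):
        return PairedGuide("p0", _mk_site(s1, 0), _mk_site(s2, 2000), "g")

    def test_template_a_length_117(self, rng):
        rec, _ = assemble_oligo(self._pair(), "A", rng)
        # fixed segments 20 + 11 + 11 + 25 = 67, plus 2x20 spacers + 10 barcode
        assert len(rec.full_sequence) == 117

    def test_template_b_length_119(self, rng):
        rec, _ = assemble_oligo(self._pair(), "B", rng)
        # fixed segments 20 + 12 + 12 + 25 = 69, plus 50 variable
        assert len(rec.full_sequence) == 119

    def test_oligo_matches_template_concatenation(self, rng):
        pair = self._pair()
        rec, barcode = assemble_oligo(pair, "A", rng)
        f5, l1, l2, f3 = OLIGO_TEMPLATES["A"]
        assert rec.full_sequence == (
            f5 + pair.guide1.expressed_spacer + l1 + barcode + l2
            + pair.guide2.expressed_spacer + f3
        )

    def test_bsmbi_spacer_refused(self, rng):
        pair = self._pair(s1="GACGCGTCTCGTACGTACGT")
        with pytest.raises(OligoAssemblyError, match="BsmBI"):
            assemble_oligo(pair, "A", rng)

    def test_bsmbi_count_is_exactly_templates_own(self, rng):
        rec, _ = assemble_oligo(self._pair(), "A", rng)
        n = rec.full_sequence.count("CGTCTC") + rec.full_sequence.count("GAGACG")
        fixed = "".join(OLIGO_TEMPLATES["A"])
        assert n == fixed.count("CGTCTC") + fixed.count("GAGACG") == 2

    def test_barcodes_unique_within_library(self, rng):
        pairs = [PairedGuide(f"p{i}", _mk_site("GACGTACGTACGTACGTACG", 0),
                             _mk_site("GCATGCATGCATGCATGCAT", 2000), "g")
                 for i in range(50)]
        _, barcodes = assemble_oligos(pairs, "A", rng)
        assert len(set(barcodes.values())) == 50


class TestExportRoundTrip:
    def test_manifest_round_trip(self, small_genome, tmp_path):
        window = TargetWindow(small_genome.name, 0, 50_000)
        cfg = DesignConfig(target_coverage=2, seed=9)
        lib = design_library(small_genome, window, cfg, n_negative=5)
        paths = export_library(lib, tmp_path / "lib")
        manifest = read_manifest(paths["manifest"])
        assert manifest.equals(design_to_manifest(lib))

    def test_bed_is_half_open(self, small_genome, tmp_path):
        window = TargetWindow(small_genome.name, 0, 50_000)
        lib = design_library(small_genome, window,
                             DesignConfig(target_coverage=2, seed=9))
        paths = export_library(lib, tmp_path / "lib")
        line = open(paths["bed"]).readline().split("\t")
        pair = lib.pairs[0]
        assert (int(line[1]), int(line[2])) == pair.deletion

    def test_empty_design_exports_headers(self, tmp_path):
        from crestkit.library_design import LibraryDesign
        lib = LibraryDesign(window=TargetWindow("g", 0, 100))
        paths = export_library(lib, tmp_path / "empty")
        manifest = read_manifest(paths["manifest"])
        assert manifest.empty
        assert list(manifest.columns)

    def test_exports_byte_identical_across_runs(self, small_genome, tmp_path):
        window = TargetWindow(small_genome.name, 0, 30_000)
        cfg = DesignConfig(target_coverage=2, seed=5)
        outs = []
        for run in ("a", "b"):
            lib = design_library(small_genome, window, cfg)
            paths = export_library(lib, tmp_path / run)
            outs.append({k: p.read_bytes() for k, p in paths.items()})
        assert outs[0] == outs[1]


def test_unsynthesizable_pairs_dropped_with_record():
    """A spacer forming a BsmBI site at a template junction is refused at
    oligo assembly; design_library drops the pair and records its id."""
    genome, _ = make_genome(60_000, seed=9)
    window = TargetWindow(genome.name, 0, 60_000)
    lib = design_library(genome, window, DesignConfig(target_coverage=3, seed=9))
    assert lib.refused  # this seed happens to produce one junction site
    manifest_ids = set(design_to_manifest(lib)["id"])
    assert not manifest_ids & set(lib.refused)
    assert len(lib.oligos) == len(lib.pairs) + len(lib.controls)


def test_filter_soundness_over_exported_library(small_genome, tmp_path):
    """Oracle re-scan: no exported spacer contains a forbidden motif."""
    window = TargetWindow(small_genome.name, 0, 50_000)
    lib = design_library(small_genome, window,
                         DesignConfig(target_coverage=2, seed=13), n_negative=5)
    manifest = design_to_manifest(lib)
    targeting = manifest[manifest["kind"] == "targeting"]
    for spacer in np.concatenate([targeting["spacer1"], targeting["spacer2"]]):
        assert not any(m in spacer for m in SPACER_FORBIDDEN_MOTIFS)


def test_pair_count_scaling_law():
    """Pair count ~= coverage x window length / mean deletion length (20%)."""
    genome, _ = make_genome(150_000, seed=21)
    window = TargetWindow(genome.name, 0, 150_000)
    cfg = DesignConfig(target_coverage=4, deletion_size_window=(2000, 3500), seed=21)
    sites = normalize_and_filter(scan_guide_sites(genome, window), cfg)
    pairs = pair_sequential(sites, window, cfg)
    mean_len = np.mean([p.deletion_length for p in pairs])
    expected = cfg.target_coverage * len(window) / mean_len
    assert abs(len(pairs) - expected) / expected < 0.20
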