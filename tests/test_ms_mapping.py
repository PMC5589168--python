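import itertools
import math
import re

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from glycopotency.glycan_model import MONOISOTOPIC, GlycanComposition, parse_glycan_name
from glycopotency import ms_mapping as mm
from glycopotency.ms_mapping import (
    ALPHA_SUBUNIT,
    BETA_SUBUNIT,
    GLYCOSITES,
    PeakList,
    QuantificationError,
    Scan,
    SitePeptide,
    chymotryptic_digest,
    default_site_peptides,
    extract_xic,
    match_ions,
    peptide_monoisotopic_mass,
    quantify_site,
    theoretical_mz,
)

# --- digestion ---------------------------------------------------------------


def oracle_digest(sequence, missed):
    """Brute-force: enumerate all (i, j) fragment spans whose boundaries are
    cleavage boundaries and which contain at most `missed` internal sites."""
    sites = [
        i + 1
        for i in range(len(sequence) - 1)
        if sequence[i] in "FYWLM" and sequence[i + 1] != "P"
    ]
    boundaries = [0] + sites + [len(sequence)]
    out = set()
    for a, b in itertools.combinations(range(len(boundaries)), 2):
        internal = b - a - 1
        if internal <= missed:
            out.add((sequence[boundaries[a]:boundaries[b]], boundaries[a] + 1, boundaries[b]))
    return out


def test_digest_simple():
    peptides = [p for p, _, _ in chymotryptic_digest("AYLFK", 0)]
    assert peptides == ["AY", "L", "F", "K"]


def test_digest_proline_rule():
    peptides = [p for p, _, _ in chymotryptic_digest("AYPK", 0)]
    assert peptides == ["AYPK"]


def test_digest_missed_cleavages():
    result = set(chymotryptic_digest("NFTAL", 1))
    assert {"NF", "TAL", "NFTAL"} <= {p for p, _, _ in result}
    assert result == oracle_digest("NFTAL", 1)


@pytest.mark.parametrize("missed", [0, 1, 2])
def test_digest_matches_bruteforce_on_subunits(missed):
    for seq in (ALPHA_SUBUNIT, BETA_SUBUNIT):
        assert set(chymotryptic_digest(seq, missed)) == oracle_digest(seq, missed)


def test_digest_rejects_unknown_residue():
    with pytest.raises(ValueError, match="position 3"):
        chymotryptic_digest("AYZK", 0)


def test_digest_positions_are_one_based_inclusive():
    for peptide, start, end in chymotryptic_digest(ALPHA_SUBUNIT, 1):
        assert ALPHA_SUBUNIT[start - 1: end] == peptide


# --- site peptides -----------------------------------------------------------


def test_default_site_peptides_cover_all_sites():
    peps = default_site_peptides()
    for site in GLYCOSITES:
        assert peps[site], f"no peptide for {site}"
        for p in peps[site]:
            sequon = p.sequence[p.glycosite_position - 1: p.glycosite_position + 2]
            assert re.fullmatch(r"N[^P][ST]", sequon)


def test_site_peptide_rejects_missing_sequon():
    with pytest.raises(ValueError, match="sequon"):
        SitePeptide.from_sequence("alpha_Asn52", "AAAAA", 1)


def test_peptide_mass_cam_cys():
    # carbamidomethylation adds 57.02146 per cysteine
    plain = peptide_monoisotopic_mass("ACK", cam_cys=False)
    fixed = peptide_monoisotopic_mass("ACK", cam_cys=True)
    assert fixed - plain == pytest.approx(57.02146, abs=1e-6)
    # residue sum + water oracle
    assert plain == pytest.approx(71.03711 + 103.00919 + 128.09496 + 18.0105646863, abs=1e-6)


# --- theoretical m/z ---------------------------------------------------------


def _dummy_peptide(mass=1000.0):
    pep = SitePeptide.from_sequence("alpha_Asn52", "NVTAAF", 1)
    object.__setattr__(pep, "backbone_mass", mass)
    return pep


def test_theoretical_mz_examples():
    pep = _dummy_peptide(1000.0)
    glycan = parse_glycan_name("A2G2S2")
    # frozen from (backbone + glycan + z*proton)/z evaluated independently;
    # the 3-decimal references carry rounded-glycan-mass dust, hence 1e-3
    assert theoretical_mz(pep, glycan, 2) == pytest.approx(1603.393, abs=1e-3)
    assert theoretical_mz(pep, glycan, 1) == pytest.approx(3205.779, abs=1e-3)


def test_theoretical_mz_bare_core_identity():
    pep = _dummy_peptide(1000.0)
    core = GlycanComposition()
    expected = pep.backbone_mass + core.residue_mass() + MONOISOTOPIC.proton
    assert theoretical_mz(pep, core, 1) == pytest.approx(expected, abs=1e-9)


def test_theoretical_mz_rejects_nonpositive_charge():
    with pytest.raises(ValueError):
        theoretical_mz(_dummy_peptide(), parse_glycan_name("A2G2S2"), 0)


# --- XIC extraction ----------------------------------------------------------


def test_extract_xic_sums_within_tolerance(simple_peaklist):
    # 500.000 and 500.001 are 2 ppm apart: both inside a 10 ppm window
    assert extract_xic(simple_peaklist, 500.0, 10.0) == pytest.approx(175.0)


def test_extract_xic_window_excludes_scans(simple_peaklist):
    assert extract_xic(simple_peaklist, 500.0, 10.0, rt_window=(5.0, 6.0)) == 0.0
    assert extract_xic(simple_peaklist, 500.0, 10.0, rt_window=(0.5, 1.5)) == pytest.approx(150.0)


def test_extract_xic_linearity(simple_peaklist):
    doubled = PeakList(
        scans=[Scan(s.retention_time, s.mz, 2 * s.intensity) for s in simple_peaklist.scans],
        scan_range=simple_peaklist.scan_range,
    )
    assert extract_xic(doubled, 500.0, 10.0) == pytest.approx(
        2 * extract_xic(simple_peaklist, 500.0, 10.0)
    )


# --- ion matching ------------------------------------------------------------


def _candidates_at(mzs, site="alpha_Asn52"):
    """Build fake candidates whose theoretical m/z equal the given values at z=1."""
    out = []
    for mz in mzs:
        pep = SitePeptide.from_sequence(site, "NVTAAF", 1)
        glycan = GlycanComposition()
        backbone = mz - glycan.residue_mass() - MONOISOTOPIC.proton
        object.__setattr__(pep, "backbone_mass", backbone)
        out.append((pep, glycan, 1))
    return out


def _single_scan(peaks):
    mzs = np.array([p[0] for p in peaks])
    ints = np.array([p[1] for p in peaks])
    return PeakList(scans=[Scan(1.0, mzs, ints)])


def test_match_within_tolerance():
    peaklist = _single_scan([(1000.005, 77.0)])
    [a] = match_ions(peaklist, _candidates_at([1000.0]), tolerance_ppm=10.0)
    assert a.ion_count == pytest.approx(77.0)
    assert a.ppm_error == pytest.approx(5.0, abs=1e-6)


def test_no_match_outside_tolerance():
    peaklist = _single_scan([(1000.020, 77.0)])
    [a] = match_ions(peaklist, _candidates_at([1000.0]), tolerance_ppm=10.0)
    assert a.ion_count == 0.0
    assert not a.observed
    assert math.isnan(a.observed_mz)


def test_nearest_candidate_wins():
    peaklist = _single_scan([(1000.003, 50.0)])
    a, b = match_ions(peaklist, _candidates_at([1000.0, 1000.008]), tolerance_ppm=10.0)
    by_theo = {round(x.theoretical_mz, 3): x for x in (a, b)}
    assert by_theo[1000.0].ion_count == pytest.approx(50.0)
    assert by_theo[1000.008].ion_count == 0.0


def test_match_empty_peaklist_warns(caplog):
    empty = PeakList(scans=[])
    with caplog.at_level("WARNING"):
        assignments = match_ions(empty, _candidates_at([1000.0]), tolerance_ppm=10.0)
    assert all(a.ion_count == 0 for a in assignments)
    assert "empty peak list" in caplog.text


def test_match_out_of_scan_range_candidate_skipped():
    peaklist = _single_scan([(1000.0, 50.0)])
    assignments = match_ions(
        peaklist, _candidates_at([1000.0, 2500.0]), tolerance_ppm=10.0
    )
    assert len(assignments) == 1  # the 2500 candidate is outside 100-2000


@settings(max_examples=25, deadline=None)
@given(st.randoms(use_true_random=False))
def test_match_stable_under_peak_permutation(rnd):
    peaks = [(1000.0 + i * 0.01 + rnd.uniform(-1e-4, 1e-4), rnd.uniform(1, 100))
             for i in range(8)]
    candidates = _candidates_at([1000.0 + i * 0.01 for i in range(8)])
    base = match_ions(_single_scan(peaks), candidates, tolerance_ppm=10.0)
    shuffled = list(peaks)
    rnd.shuffle(shuffled)
    perm = match_ions(_single_scan(shuffled), candidates, tolerance_ppm=10.0)
    key = lambda a: (a.theoretical_mz, a.charge)
    for x, y in zip(sorted(base, key=key), sorted(perm, key=key)):
        assert x.ion_count == pytest.approx(y.ion_count)


# --- quantitation ------------------------------------------------------------


def _assignment(site, peptide_seq, glycan_name, charge, count):
    pep = SitePeptide.from_sequence(site, peptide_seq, peptide_seq.index("N") + 1)
    return mm.GlycopeptideAssignment(
        site_id=site, peptide=pep, glycan=parse_glycan_name(glycan_name),
        charge=charge, theoretical_mz=1000.0, observed_mz=1000.0,
        ppm_error=0.0, ion_count=count,
    )


def test_quantify_simple_percentages():
    assignments = [
        _assignment("alpha_Asn52", "NVTAAF", "A2G2S2", 2, 300.0),
        _assignment("alpha_Asn52", "NVTAAF", "A3G3S3", 2, 100.0),
    ]
    dist = quantify_site(assignments, "alpha_Asn52")
    assert dist.entries == pytest.approx({"A2G2S2": 75.0, "A3G3S3": 25.0})


def test_quantify_scale_invariance():
    def dist_for(scale):
        assignments = [
            _assignment("alpha_Asn52", "NVTAAF", "A2G2S2", 2, 300.0 * scale),
            _assignment("alpha_Asn52", "NVTAAF", "A3G3S3", 2, 100.0 * scale),
        ]
        return quantify_site(assignments, "alpha_Asn52").entries

    assert dist_for(1.0) == pytest.approx(dist_for(7.31))


def test_quantify_pools_charges():
    assignments = [
        _assignment("alpha_Asn52", "NVTAAF", "A2G2S2", 2, 60.0),
        _assignment("alpha_Asn52", "NVTAAF", "A2G2S2", 3, 40.0),
        _assignment("alpha_Asn52", "NVTAAF", "A3G3S3", 2, 100.0),
    ]
    dist = quantify_site(assignments, "alpha_Asn52")
    # direct summation oracle: A2G2S2 pools 60+40 = 100 of 200 total
    assert dist.entries["A2G2S2"] == pytest.approx(50.0)
    assert dist.entries["A3G3S3"] == pytest.approx(50.0)


def test_quantify_sums_to_100():
    rng = np.random.default_rng(5)
    assignments = [
        _assignment("alpha_Asn52", "NVTAAF", name, z, rng.uniform(1, 500))
        for name in ("A2G2S1", "A2G2S2", "A3G3S3")
        for z in (2, 3)
    ]
    dist = quantify_site(assignments, "alpha_Asn52")
    assert dist.total() == pytest.approx(100.0, abs=1e-6)


def test_quantify_backbone_selection_default(caplog):
    # two backbones: default keeps only the higher-ion-count one
    assignments = [
        _assignment("alpha_Asn52", "NVTAAF", "A2G2S2", 2, 900.0),
        _assignment("alpha_Asn52", "KNVTAAF", "A3G3S3", 2, 100.0),
    ]
    with caplog.at_level("WARNING"):
        dist = quantify_site(assignments, "alpha_Asn52")
    assert dist.entries == pytest.approx({"A2G2S2": 100.0})
    assert "backbone" in caplog.text

    pooled = quantify_site(assignments, "alpha_Asn52", pool_backbones=True)
    assert pooled.entries == pytest.approx({"A2G2S2": 90.0, "A3G3S3": 10.0})


def test_quantify_all_zero_raises():
    assignments = [_assignment("alpha_Asn52", "NVTAAF", "A2G2S2", 2, 0.0)]
    with pytest.raises(QuantificationError, match="no quantifiable species"):
        quantify_site(assignments, "alpha_Asn52")


# --- peak list I/O and invariants -------------------------------------------


def test_peaklist_csv_roundtrip(tmp_path, simple_peaklist):
    path = tmp_path / "peaks.csv"
    simple_peaklist.to_csv(path)
    loaded = PeakList.from_csv(path)
    assert len(loaded) == len(simple_peaklist)
    for a, b in zip(loaded.scans, simple_peaklist.scans):
        assert a.retention_time == pytest.approx(b.retention_time)
        np.testing.assert_allclose(np.sort(a.mz), np.sort(b.mz), atol=1e-6)


def test_peaklist_rejects_decreasing_rt():
    with pytest.raises(ValueError, match="non-decreasing"):
        PeakList(scans=[Scan(2.0, [500.0], [1.0]), Scan(1.0, [500.0], [1.0])])


def test_peaklist_rejects_out_of_range_mz():
    with pytest.raises(ValueError, match="scan range"):
        PeakList(scans=[Scan(1.0, [2500.0], [1.0])], scan_range=(100.0, 2000.0))
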