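"""Allele typing: scheme validation, alignment mapping, calling, batch runs."""

import copy

import pytest
import yaml
from hypothesis import given, strategies as st

import ompakit as ok
from ompakit.alleles import ALIGN_SCORING, SchemeValidationError, dump_scheme


# ---------------------------------------------------------------------------
# scheme loading
# ---------------------------------------------------------------------------

def test_bundled_scheme_shape(scheme):
    assert set(scheme.nterm_patterns) == {"I", "II", "III", "IV", "V", "VI", "VII"}
    assert set(scheme.cterm_patterns) == {"alpha", "beta", "gamma", "delta"}


def test_loop2_pattern_partition(scheme):
    """I/IV/V/VII carry SVE at loop 2, II/III/VI carry DNI."""
    sve = {pid for pid, pat in scheme.nterm_patterns.items() if pat["loop2"] == "SVE"}
    dni = {pid for pid, pat in scheme.nterm_patterns.items() if pat["loop2"] == "DNI"}
    assert sve == {"I", "IV", "V", "VII"}
    assert dni == {"II", "III", "VI"}


def test_loop3_length_polymorphism(scheme):
    """VI and VII are the only patterns with both the loop-1 D variant and the
    short (7-residue) loop 3; II, III and V carry the long run."""
    short = {pid for pid, p in scheme.nterm_patterns.items() if len(p["loop3"]) == 7}
    d_loop1 = {pid for pid, p in scheme.nterm_patterns.items() if p["loop1"] == "D"}
    assert short & d_loop1 == {"VI", "VII"}
    assert {"II", "III", "V"} <= {pid for pid, p in scheme.nterm_patterns.items()
                                  if len(p["loop3"]) == 8}


def test_empty_source_rejected(reference):
    with pytest.raises(SchemeValidationError):
        ok.load_scheme("", reference=reference)


def test_alpha_must_match_reference(reference, scheme):
    data = yaml.safe_load(dump_scheme(scheme))
    data["cterm_patterns"]["alpha"]["203"] = "Q"
    with pytest.raises(SchemeValidationError, match="alpha"):
        ok.load_scheme(data, reference=reference)


def test_delta_alpha_difference_enforced(reference, scheme):
    data = yaml.safe_load(dump_scheme(scheme))
    data["cterm_patterns"]["delta"]["175"] = "W"
    with pytest.raises(SchemeValidationError, match="delta"):
        ok.load_scheme(data, reference=reference)


def test_duplicate_patterns_rejected(reference, scheme):
    data = yaml.safe_load(dump_scheme(scheme))
    data["nterm_patterns"]["II"] = dict(data["nterm_patterns"]["III"])
    with pytest.raises(SchemeValidationError, match="identical"):
        ok.load_scheme(data, reference=reference)


def test_scheme_roundtrip(reference, scheme):
    """Serialize-then-load returns a field-identical scheme."""
    again = ok.load_scheme(yaml.safe_load(dump_scheme(scheme)), reference=reference)
    assert again.nterm_patterns == scheme.nterm_patterns
    assert again.cterm_patterns == scheme.cterm_patterns
    assert again.nterm_sites == scheme.nterm_sites
    assert again.cterm_sites == scheme.cterm_sites


# ---------------------------------------------------------------------------
# alignment and position mapping
# ---------------------------------------------------------------------------

def _gotoh_score(a: str, b: str) -> float:
    """Independent affine-gap global alignment score (oracle)."""
    match, mismatch = ALIGN_SCORING["match"], ALIGN_SCORING["mismatch"]
    go, ge = ALIGN_SCORING["gap_open"], ALIGN_SCORING["gap_extend"]
    NEG = float("-inf")
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = go + ge * (i - 1)
    for j in range(1, m + 1):
        Y[0][j] = go + ge * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + go, X[i - 1][j] + ge, Y[i - 1][j] + go)
            Y[i][j] = max(M[i][j - 1] + go, Y[i][j - 1] + ge, X[i][j - 1] + go)
    return max(M[n][m], X[n][m], Y[n][m])


def test_self_alignment_is_identity(reference):
    pmap = ok.align_to_reference(reference.mature_sequence, reference)
    assert all(pmap[p] == p for p in range(1, 326))
    assert pmap.identity == 1.0 and not pmap.trimmed


def test_loop3_deletion_shifts_downstream_by_one(reference):
    """Deleting one loop-3 residue shifts every later position by exactly 1,
    and the aligner attains the independent affine-gap optimum."""
    pos = 101  # inside loop 3, outside the run site
    seq = reference.mature_sequence
    query = seq[: pos - 1] + seq[pos:]
    pmap = ok.align_to_reference(query, reference)
    assert _gotoh_score(seq, query) == pytest.approx(324 * 1 + (-5))
    assert all(pmap[p] == p for p in range(1, pos))
    assert pmap[pos] is None
    assert all(pmap[p] == p - 1 for p in range(pos + 1, 326))


def test_precursor_is_trimmed_to_identity(reference):
    pmap = ok.align_to_reference(reference.precursor_sequence, reference)
    assert pmap.trimmed
    assert all(pmap[p] == p for p in range(1, 326))


def test_distant_sequence_rejected(reference):
    shuffled = reference.mature_sequence[::-1]
    with pytest.raises(ok.NotOmpALikeError):
        ok.align_to_reference(shuffled, reference)


def test_invalid_characters_rejected(reference):
    with pytest.raises(ValueError, match="non-amino-acid"):
        ok.align_to_reference("ACDX" * 90, reference)


# ---------------------------------------------------------------------------
# profiles and calls
# ---------------------------------------------------------------------------

def test_k12_profile_matches_alpha(reference, scheme):
    prof = ok.extract_variant_profile(reference.mature_sequence, reference, scheme)
    assert prof.cterm == scheme.cterm_patterns["alpha"]
    assert set(prof.non_classifying) == {93, 129, 161}


def test_single_substitution_only_changes_site_203(reference, scheme):
    seq = reference.mature_sequence
    mutated = seq[:202] + "T" + seq[203:]
    base = ok.extract_variant_profile(seq, reference, scheme)
    prof = ok.extract_variant_profile(mutated, reference, scheme)
    assert prof.cterm[203] == "T" and base.cterm[203] == "N"
    assert prof.cterm[175] == base.cterm[175] and prof.cterm[251] == base.cterm[251]
    assert prof.nterm == base.nterm


def test_k12_is_called_I_alpha(reference, scheme):
    call = ok.type_sequence(reference.mature_sequence, reference, scheme)
    assert (call.nterm, call.cterm) == ("I", "alpha")
    assert call.nterm_mismatches == 0 and call.cterm_mismatches == 0


def test_all_exemplars_roundtrip(reference, scheme):
    for nterm, cterm in ok.EXEMPLAR_ALLELES:
        seq = ok.build_allele_sequence(nterm, cterm, scheme, reference)
        call = ok.type_sequence(seq, reference, scheme)
        assert (call.nterm, call.cterm) == (nterm, cterm)


def test_novel_site_gives_nearest_at_distance_one(reference, scheme):
    """A single off-pattern residue at one loop site yields a novel call whose
    nearest patterns, found exhaustively, sit at mismatch distance 1."""
    seq = ok.build_allele_sequence("I", "alpha", scheme, reference)
    loop1 = scheme.nterm_site("loop1")
    mutated = seq[: loop1.start - 1] + "W" + seq[loop1.start :]
    call = ok.type_sequence(mutated, reference, scheme)
    assert call.nterm == "novel" and call.nterm_mismatches == 1
    # exhaustive oracle: distance of each pattern from the observed profile
    prof = ok.extract_variant_profile(mutated, reference, scheme)
    dists = {
        pid: sum(prof.nterm[s] != pat[s] for s in pat)
        for pid, pat in scheme.nterm_patterns.items()
    }
    expected = {pid for pid, d in dists.items() if d == min(dists.values())}
    assert set(call.nearest_nterm) == expected


def test_domain_independence(reference, scheme):
    """C-terminal-only edits never change the nterm call and vice versa."""
    seq = ok.build_allele_sequence("I", "alpha", scheme, reference)
    delta_like = seq[:202] + "T" + seq[203:250] + "D" + seq[251:]
    call = ok.type_sequence(delta_like, reference, scheme)
    assert call.nterm == "I" and call.cterm == "delta"
    loop4 = scheme.nterm_site("loop4")
    loop_edit = seq[: loop4.start - 1] + "L" + seq[loop4.start :]
    call2 = ok.type_sequence(loop_edit, reference, scheme)
    assert call2.cterm == "alpha" and call2.nterm == "IV"


@given(st.integers(1, 2), st.booleans())
def test_loop3_indel_robustness(k, insert):
    """Indels of k <= 2 residues inside loop 3 leave the C-terminal site
    calls unchanged (positions re-located through the alignment)."""
    reference = ok.load_reference()
    scheme = ok.load_scheme(reference=reference)
    seq = reference.mature_sequence
    pos = 102
    if insert:
        mutated = seq[:pos] + "G" * k + seq[pos:]
    else:
        mutated = seq[: pos - 1] + seq[pos - 1 + k :]
    call = ok.type_sequence(mutated, reference, scheme)
    assert call.cterm == "alpha" and call.cterm_mismatches == 0


def test_oracle_equivalence_near_reference(reference, scheme):
    """For sequences within <=3 substitutions of the reference, call_allele
    agrees with exhaustive pattern-table comparison."""
    import numpy as np

    rng = np.random.default_rng(11)
    seq = reference.mature_sequence
    residues = "ACDEFGHIKLMNPQRSTVWY"
    for _ in range(25):
        s = list(seq)
        for pos in rng.choice(325, size=rng.integers(1, 4), replace=False):
            s[pos] = residues[rng.integers(20)]
        query = "".join(s)
        call = ok.type_sequence(query, reference, scheme)
        prof = ok.extract_variant_profile(query, reference, scheme)
        for domain, patterns, got in (
            ("nterm", scheme.nterm_patterns, call.nterm),
            ("cterm", scheme.cterm_patterns, call.cterm),
        ):
            observed = getattr(prof, domain)
            dists = {pid: sum(observed[k] != pat[k] for k in pat)
                     for pid, pat in patterns.items()}
            exact = [pid for pid, d in dists.items() if d == 0]
            assert got == (exact[0] if exact else "novel")


# ---------------------------------------------------------------------------
# power-allele projection and batch typing
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "nterm,cterm,expected",
    [("I", "alpha", "ompA1"), ("IV", "beta", "ompA1"), ("VII", "beta", "ompA1"),
     ("II", "alpha", "ompA2"), ("III", "gamma", "ompA2"),
     ("V", "alpha", "unmapped"), ("VI", "alpha", "unmapped"), ("novel", "alpha", "unmapped")],
)
def test_power_allele_projection(nterm, cterm, expected):
    call = ok.AlleleCall(source_id="x", nterm=nterm, cterm=cterm,
                         nterm_mismatches=0, cterm_mismatches=0)
    assert ok.map_to_power_alleles(call) == expected


def test_batch_type_exemplars(tmp_path, reference, scheme):
    records = [(f"{n}_{c}", ok.build_allele_sequence(n, c, scheme, reference))
               for n, c in ok.EXEMPLAR_ALLELES]
    fasta = tmp_path / "ex.fasta"
    fasta.write_text(ok.records_to_fasta(records))
    table = ok.batch_type(fasta, reference, scheme)
    assert list(table["id"]) == [r[0] for r in records]  # input order kept
    assert list(zip(table["nterm"], table["cterm"])) == list(ok.EXEMPLAR_ALLELES)
    assert (table["nterm_mismatches"] == 0).all()


def test_batch_type_repeated_record_is_deterministic(tmp_path, reference):
    fasta = tmp_path / "rep.fasta"
    fasta.write_text(ok.records_to_fasta([("a", reference.mature_sequence),
                                          ("b", reference.mature_sequence)]))
    table = ok.batch_type(fasta)
    assert table.iloc[0]["nterm"] == table.iloc[1]["nterm"] == "I"


def test_batch_type_bad_record_continues(tmp_path, reference, scheme):
    fasta = tmp_path / "bad.fasta"
    fasta.write_text(f">good\n{reference.mature_sequence}\n>bad\nACDEFGHIKX\n")
    table = ok.batch_type(fasta, reference, scheme)
    assert table.iloc[0]["nterm"] == "I"
    assert table.iloc[1]["nterm"] == "error"
    assert table.iloc[1]["flags"].startswith("error:")


def test_batch_type_empty_file_warns(tmp_path):
    fasta = tmp_path / "empty.fasta"
    fasta.write_text("")
    with pytest.warns(UserWarning, match="no FASTA records"):
        table = ok.batch_type(fasta)
    assert table.empty
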