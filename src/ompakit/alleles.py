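"""OmpA allele typing.

Maps query OmpA protein sequences onto the mature K-12 reference coordinate
system by global pairwise alignment, extracts the residues at the
classification sites, and assigns the (N-terminal I-VII, C-terminal
alpha-delta) allele bin. Loop sites are residue runs compared on exact
equality (length included), which is what lets a 7- vs 8-residue loop 3
separate patterns. The two domains are always called independently.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml
from Bio import Align, SeqIO

from .reference import AMINO_ACIDS, OmpAReference, load_reference

NTERM_IDS = ("I", "II", "III", "IV", "V", "VI", "VII")
CTERM_IDS = ("alpha", "beta", "gamma", "delta")
NOVEL = "novel"

# ompA1/ompA2 nomenclature of Power et al., defined over the outer-loop bins.
POWER_MAP = {"I": "ompA1", "IV": "ompA1", "VII": "ompA1", "II": "ompA2", "III": "ompA2"}


class SchemeValidationError(ValueError):
    pass


class NotOmpALikeError(ValueError):
    """Query is below the identity floor against the mature reference."""


# ---------------------------------------------------------------------------
# Scheme
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SiteDefinition:
    """A classification site: a single position or a residue run on the
    mature reference; `variable_length` marks the loop-3 length polymorphism."""

    name: str
    start: int
    end: int
    variable_length: bool = False

    @property
    def is_run(self) -> bool:
        return self.end > self.start or self.variable_length


@dataclass(frozen=True)
class ClassificationScheme:
    nterm_sites: tuple[SiteDefinition, ...]
    cterm_sites: tuple[int, ...]
    nterm_patterns: dict[str, dict[str, str]]   # pattern id -> site name -> run
    cterm_patterns: dict[str, dict[int, str]]   # pattern id -> position -> residue
    provenance: str = ""
    name: str = ""
    version: str = ""

    def nterm_site(self, name: str) -> SiteDefinition:
        for s in self.nterm_sites:
            if s.name == name:
                return s
        raise KeyError(name)


def _validate_scheme(scheme: ClassificationScheme, reference: OmpAReference) -> None:
    site_names = [s.name for s in scheme.nterm_sites]
    for pid, pat in scheme.nterm_patterns.items():
        missing = [n for n in site_names if n not in pat]
        if missing:
            raise SchemeValidationError(f"nterm pattern {pid} missing sites {missing}")
    for pid, pat in scheme.cterm_patterns.items():
        missing = [p for p in scheme.cterm_sites if p not in pat]
        if missing:
            raise SchemeValidationError(f"cterm pattern {pid} missing positions {missing}")
    for label, pats in (("nterm", scheme.nterm_patterns), ("cterm", scheme.cterm_patterns)):
        seen: dict[tuple, str] = {}
        for pid, pat in pats.items():
            key = tuple(sorted((str(k), v) for k, v in pat.items()))
            if key in seen:
                raise SchemeValidationError(f"{label} patterns {seen[key]} and {pid} are identical")
            seen[key] = pid
    if "alpha" in scheme.cterm_patterns:
        for pos, res in scheme.cterm_patterns["alpha"].items():
            if reference.residue(pos) != res:
                raise SchemeValidationError(
                    f"cterm pattern alpha residue {res} at {pos} does not match "
                    f"reference {reference.residue(pos)}"
                )
    if {"alpha", "delta"} <= scheme.cterm_patterns.keys():
        alpha, delta = scheme.cterm_patterns["alpha"], scheme.cterm_patterns["delta"]
        diff = sorted(p for p in scheme.cterm_sites if alpha[p] != delta[p])
        if diff != [203, 251]:
            raise SchemeValidationError(
                f"delta must differ from alpha at exactly 203 and 251, differs at {diff}"
            )


def load_scheme(
    source: str | Path | dict | None = None,
    reference: OmpAReference | None = None,
) -> ClassificationScheme:
    """Load and validate a classification scheme.

    `source` is a YAML path, a YAML string, or an already-parsed mapping;
    ``None`` loads the bundled scheme. Schemes violating the structural
    invariants raise :class:`SchemeValidationError` naming the offender.
    """
    if reference is None:
        reference = load_reference()
    if source is None:
        raw = resources.files("ompakit.data").joinpath("scheme.yaml").read_text("utf-8")
        data = yaml.safe_load(raw)
    elif isinstance(source, dict):
        data = source
    else:
        p = Path(str(source))
        text = p.read_text("utf-8") if str(source) and p.is_file() else str(source)
        data = yaml.safe_load(text)
    if not data:
        raise SchemeValidationError("empty scheme source")
    try:
        sites = tuple(
            SiteDefinition(
                name=n,
                start=int(d["start"]),
                end=int(d["end"]),
                variable_length=bool(d.get("variable_length", False)),
            )
            for n, d in data["nterm_sites"].items()
        )
        cterm_sites = tuple(int(p) for p in data["cterm_sites"])
        nterm_patterns = {
            str(pid): {str(k): str(v) for k, v in pat.items()}
            for pid, pat in data["nterm_patterns"].items()
        }
        cterm_patterns = {
            str(pid): {int(k): str(v) for k, v in pat.items()}
            for pid, pat in data["cterm_patterns"].items()
        }
    except KeyError as exc:
        raise SchemeValidationError(f"scheme source missing section {exc}") from exc
    scheme = ClassificationScheme(
        nterm_sites=sites,
        cterm_sites=cterm_sites,
        nterm_patterns=nterm_patterns,
        cterm_patterns=cterm_patterns,
        provenance=str(data.get("provenance", "")),
        name=str(data.get("name", "")),
        version=str(data.get("version", "")),
    )
    _validate_scheme(scheme, reference)
    return scheme


def dump_scheme(scheme: ClassificationScheme) -> str:
    """Serialize a scheme back to YAML (round-trips through load_scheme)."""
    data = {
        "name": scheme.name,
        "version": scheme.version,
        "provenance": scheme.provenance,
        "nterm_sites": {
            s.name: (
                {"start": s.start, "end": s.end, "variable_length": True}
                if s.variable_length
                else {"start": s.start, "end": s.end}
            )
            for s in scheme.nterm_sites
        },
        "cterm_sites": list(scheme.cterm_sites),
        "nterm_patterns": {k: dict(v) for k, v in scheme.nterm_patterns.items()},
        "cterm_patterns": {k: {str(p): r for p, r in v.items()} for k, v in scheme.cterm_patterns.items()},
    }
    return yaml.safe_dump(data, sort_keys=False)


# ---------------------------------------------------------------------------
# Alignment / position map
# ---------------------------------------------------------------------------

#: Documented global-alignment scoring: match +1, mismatch -1, gap open -5,
#: gap extend -1 (a gap of length L costs 5 + (L-1)). Adequate for the
#: >70 %-identity inputs this scheme is defined for.
ALIGN_SCORING = {"match": 1.0, "mismatch": -1.0, "gap_open": -5.0, "gap_extend": -1.0}

DEFAULT_IDENTITY_FLOOR = 0.70
_PRECURSOR_MIN_LENGTH = 340


@dataclass(frozen=True)
class PositionMap:
    """Reference(mature, 1-based) -> query(1-based) coordinate map.

    `pairs[p]` is the query position aligned to reference position p, or
    ``None`` where the reference residue is deleted in the query. Defined for
    every reference position; strictly increasing where defined.
    """

    pairs: dict[int, int | None]
    query_sequence: str
    identity: float
    trimmed: bool = False

    def __getitem__(self, position: int) -> int | None:
        return self.pairs[position]

    def residue(self, position: int) -> str:
        q = self.pairs[position]
        return "-" if q is None else self.query_sequence[q - 1]


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = ALIGN_SCORING["match"]
    aligner.mismatch_score = ALIGN_SCORING["mismatch"]
    aligner.open_gap_score = ALIGN_SCORING["gap_open"]
    aligner.extend_gap_score = ALIGN_SCORING["gap_extend"]
    return aligner


def align_to_reference(
    query: str,
    reference: OmpAReference | None = None,
    identity_floor: float = DEFAULT_IDENTITY_FLOOR,
) -> PositionMap:
    """Globally align a query protein to the mature reference.

    Precursor inputs (length >= 340 whose first 21 residues resemble the
    signal peptide) are trimmed first and flagged. Queries whose identity to
    the reference falls below `identity_floor` raise
    :class:`NotOmpALikeError` — sequences outside the E. coli classification
    system must fail here rather than be force-binned.
    """
    if reference is None:
        reference = load_reference()
    query = query.strip().upper()
    bad = set(query) - AMINO_ACIDS
    if bad:
        raise ValueError(f"non-amino-acid characters in query: {sorted(bad)}")
    trimmed = False
    if len(query) >= _PRECURSOR_MIN_LENGTH:
        spl = reference.signal_peptide_length
        prefix = query[:spl]
        same = sum(a == b for a, b in zip(prefix, reference.signal_peptide))
        if same / spl >= 0.5:
            query = query[spl:]
            trimmed = True
    aligner = _make_aligner()
    alignment = aligner.align(reference.mature_sequence, query)[0]
    pairs: dict[int, int | None] = {p: None for p in range(1, len(reference.mature_sequence) + 1)}
    matches = 0
    ref_blocks, query_blocks = alignment.aligned
    for (rs, re), (qs, qe) in zip(ref_blocks, query_blocks):
        for offset in range(re - rs):
            rpos, qpos = rs + offset + 1, qs + offset + 1
            pairs[rpos] = qpos
            if reference.mature_sequence[rpos - 1] == query[qpos - 1]:
                matches += 1
    identity = matches / len(reference.mature_sequence)
    if identity < identity_floor:
        raise NotOmpALikeError(
            f"query identity {identity:.2f} below floor {identity_floor:.2f}; "
            "not OmpA-like under this classification system"
        )
    return PositionMap(pairs=pairs, query_sequence=query, identity=identity, trimmed=trimmed)


# ---------------------------------------------------------------------------
# Variant profiles and calls
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantProfile:
    """Observed residues (or residue runs at loop sites) at every
    classification site of one query sequence."""

    source_id: str
    nterm: dict[str, str]          # site name -> residue run ("-" for gap)
    cterm: dict[int, str]          # position -> residue
    non_classifying: dict[int, str] = field(default_factory=dict)
    trimmed: bool = False


def _run_at(site: SiteDefinition, pmap: PositionMap) -> str:
    """Query residues spanning a reference run, located via the nearest
    mapped flanking positions so loop-length changes are captured."""
    n_ref = len(pmap.pairs)
    left = site.start - 1
    while left >= 1 and pmap[left] is None:
        left -= 1
    right = site.end + 1
    while right <= n_ref and pmap[right] is None:
        right += 1
    q_left = pmap[left] if left >= 1 else 0
    q_right = pmap[right] if right <= n_ref else len(pmap.query_sequence) + 1
    if q_left is None or q_right is None:
        return "-"
    run = pmap.query_sequence[q_left : q_right - 1]
    return run if run else "-"


def extract_variant_profile(
    query: str,
    reference: OmpAReference | None = None,
    scheme: ClassificationScheme | None = None,
    source_id: str = "",
) -> VariantProfile:
    """Extract the residues at every classification site of `query`.

    Loop (run) sites use flanking-anchor extraction so insertions and
    deletions inside the loop do not shift the downstream single-residue
    sites; those are read through the position map. Non-classifying
    positions (93/129/161) are recorded but never influence the call.
    """
    if reference is None:
        reference = load_reference()
    if scheme is None:
        scheme = load_scheme(reference=reference)
    pmap = align_to_reference(query, reference)
    nterm = {site.name: _run_at(site, pmap) for site in scheme.nterm_sites}
    cterm = {pos: pmap.residue(pos) for pos in scheme.cterm_sites}
    extra = {pos: pmap.residue(pos) for pos in reference.non_classifying_positions()}
    return VariantProfile(
        source_id=source_id, nterm=nterm, cterm=cterm, non_classifying=extra, trimmed=pmap.trimmed
    )


@dataclass(frozen=True)
class AlleleCall:
    """(N-terminal, C-terminal) bin assignment for one sequence."""

    source_id: str
    nterm: str                      # pattern id or "novel"
    cterm: str
    nterm_mismatches: int
    cterm_mismatches: int
    nearest_nterm: tuple[str, ...] = ()
    nearest_cterm: tuple[str, ...] = ()
    flags: tuple[str, ...] = ()

    @property
    def label(self) -> str:
        return f"({self.nterm}, {self.cterm})"


def _call_domain(
    observed: dict, patterns: dict[str, dict], domain: str
) -> tuple[str, int, tuple[str, ...], list[str]]:
    distances: dict[str, int] = {}
    for pid, pat in patterns.items():
        mism = 0
        for key, expected in pat.items():
            if key not in observed:
                raise ValueError(f"profile missing {domain} site {key}")
            if observed[key] != expected:
                mism += 1  # unequal-length loop runs count as one mismatch
        distances[pid] = mism
    best = min(distances.values())
    nearest = tuple(pid for pid, d in distances.items() if d == best)
    flags: list[str] = []
    if best == 0:
        return nearest[0], 0, (), flags
    if len(nearest) >= 2:
        flags.append(f"ambiguous-{domain}-tie")
    return NOVEL, best, nearest, flags


def call_allele(profile: VariantProfile, scheme: ClassificationScheme) -> AlleleCall:
    """Assign (I-VII, alpha-delta) by exact site matching; report the nearest
    pattern(s) by site-mismatch count when no pattern matches exactly."""
    nterm, n_mism, n_near, n_flags = _call_domain(profile.nterm, scheme.nterm_patterns, "nterm")
    cterm, c_mism, c_near, c_flags = _call_domain(profile.cterm, scheme.cterm_patterns, "cterm")
    flags = list(n_flags) + list(c_flags)
    if profile.trimmed:
        flags.append("signal-peptide-trimmed")
    if "-" in profile.nterm.values() or "-" in profile.cterm.values():
        flags.append("gap-at-site")
    return AlleleCall(
        source_id=profile.source_id,
        nterm=nterm,
        cterm=cterm,
        nterm_mismatches=n_mism,
        cterm_mismatches=c_mism,
        nearest_nterm=n_near,
        nearest_cterm=c_near,
        flags=tuple(flags),
    )


def type_sequence(
    query: str,
    reference: OmpAReference | None = None,
    scheme: ClassificationScheme | None = None,
    source_id: str = "",
) -> AlleleCall:
    """Convenience: align, profile and call one sequence."""
    if reference is None:
        reference = load_reference()
    if scheme is None:
        scheme = load_scheme(reference=reference)
    profile = extract_variant_profile(query, reference, scheme, source_id=source_id)
    return call_allele(profile, scheme)


def map_to_power_alleles(call: AlleleCall) -> str:
    """Project an N-terminal bin onto the two-allele ompA1/ompA2 nomenclature:
    I/IV/VII -> ompA1, II/III -> ompA2, anything else -> unmapped."""
    return POWER_MAP.get(call.nterm, "unmapped")


# ---------------------------------------------------------------------------
# Sequence construction and batch typing
# ---------------------------------------------------------------------------

def build_allele_sequence(
    nterm: str,
    cterm: str,
    scheme: ClassificationScheme | None = None,
    reference: OmpAReference | None = None,
) -> str:
    """Reconstruct the mature sequence of an allele by editing the reference
    to the pattern's site residues (edits applied right-to-left so loop-length
    changes never shift pending coordinates)."""
    if reference is None:
        reference = load_reference()
    if scheme is None:
        scheme = load_scheme(reference=reference)
    edits: list[tuple[int, int, str]] = []  # (start, end, replacement), 1-based
    for site in scheme.nterm_sites:
        edits.append((site.start, site.end, scheme.nterm_patterns[nterm][site.name]))
    for pos in scheme.cterm_sites:
        edits.append((pos, pos, scheme.cterm_patterns[cterm][pos]))
    seq = reference.mature_sequence
    for start, end, repl in sorted(edits, reverse=True):
        seq = seq[: start - 1] + repl + seq[end:]
    return seq


def batch_type(
    fasta_path: str | Path,
    reference: OmpAReference | None = None,
    scheme: ClassificationScheme | None = None,
) -> pd.DataFrame:
    """Type every record of a protein FASTA file.

    Returns one row per record, in input order, with columns
    ``id,nterm,cterm,nterm_mismatches,cterm_mismatches,flags``. Records that
    fail (non-amino-acid characters, below the identity floor) produce a
    row-level error entry and the run continues.
    """
    if reference is None:
        reference = load_reference()
    if scheme is None:
        scheme = load_scheme(reference=reference)
    text = Path(fasta_path).read_text("utf-8") if not hasattr(fasta_path, "read") else fasta_path.read()
    records = list(SeqIO.parse(io.StringIO(text), "fasta"))
    if not records:
        warnings.warn(f"no FASTA records found in {fasta_path}", stacklevel=2)
    rows = []
    for rec in records:
        try:
            call = type_sequence(str(rec.seq), reference, scheme, source_id=rec.id)
            rows.append(
                {
                    "id": rec.id,
                    "nterm": call.nterm,
                    "cterm": call.cterm,
                    "nterm_mismatches": call.nterm_mismatches,
                    "cterm_mismatches": call.cterm_mismatches,
                    "flags": ";".join(call.flags),
                }
            )
        except (ValueError, NotOmpALikeError) as exc:
            rows.append(
                {
                    "id": rec.id,
                    "nterm": "error",
                    "cterm": "error",
                    "nterm_mismatches": -1,
                    "cterm_mismatches": -1,
                    "flags": f"error:{exc}",
                }
            )
    columns = ["id", "nterm", "cterm", "nterm_mismatches", "cterm_mismatches", "flags"]
    return pd.DataFrame(rows, columns=columns)
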