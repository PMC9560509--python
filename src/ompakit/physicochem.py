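"""Sequence-based physicochemical prediction for OmpA segments.

Net charge of a peptide segment at a given pH is computed with the
Henderson–Hasselbalch equation,

    Q(pH) = sum_basic 1/(1 + 10^(pH - pKa)) - sum_acidic 1/(1 + 10^(pKa - pH)),

with terminal groups contributing only on request (surface loops are internal
stretches of the chain and carry no free termini). The hydrophobicity index
is an aggregate (sum or mean) of a per-residue scale; the default is
Kyte–Doolittle in mean mode (the GRAVY score). Both the pKa set and the scale
are data, not code: the study names the tools it used but not their
constants, so exact numeric reproduction of the published per-loop table is a
calibration exercise — its *equality structure* across alleles is what this
module reproduces and tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .alleles import (
    CTERM_IDS,
    NTERM_IDS,
    ClassificationScheme,
    build_allele_sequence,
    load_scheme,
)
from .reference import AMINO_ACIDS, OmpAReference, load_reference

#: The seven exemplar alleles characterized in a single K-12 background.
EXEMPLAR_ALLELES = (
    ("I", "alpha"),
    ("II", "alpha"),
    ("III", "gamma"),
    ("IV", "beta"),
    ("V", "alpha"),
    ("VI", "alpha"),
    ("VII", "beta"),
)

N_TERMINAL_LOOPS = ("loop1", "loop2", "loop3", "loop4")
C_TERMINAL_LOOPS = ("loop5", "loop6", "loop7", "loop8")


class UnknownResidueError(ValueError):
    pass


@dataclass(frozen=True)
class PkaTable:
    """Side-chain and terminal pKa values with acid/base polarity."""

    acidic: dict[str, float]   # residues whose deprotonated form is -1
    basic: dict[str, float]    # residues whose protonated form is +1
    n_terminus: float
    c_terminus: float
    name: str = ""

    def __post_init__(self) -> None:
        for label, pka in [*self.acidic.items(), *self.basic.items(),
                           ("n_terminus", self.n_terminus), ("c_terminus", self.c_terminus)]:
            if not 0.0 < float(pka) < 14.0:
                raise ValueError(f"pKa for {label} out of (0, 14): {pka}")


@dataclass(frozen=True)
class HydrophobicityScale:
    values: dict[str, float]
    aggregation: str = "mean"   # "mean" | "sum"
    name: str = ""

    def __post_init__(self) -> None:
        missing = AMINO_ACIDS - self.values.keys()
        if missing:
            raise ValueError(f"scale {self.name or '?'} missing residues {sorted(missing)}")
        if self.aggregation not in ("mean", "sum"):
            raise ValueError(f"unknown aggregation mode {self.aggregation!r}")


def _load_yaml(source: str | Path | None, default: str) -> dict:
    if source is None:
        text = resources.files("ompakit.data").joinpath(default).read_text("utf-8")
    else:
        p = Path(source)
        text = p.read_text("utf-8") if p.exists() else str(source)
    return yaml.safe_load(text)


def load_pka_table(source: str | Path | None = None) -> PkaTable:
    """Load a pKa set (default: bundled Protein Calculator-style values)."""
    data = _load_yaml(source, "pka_protcalc.yaml")
    return PkaTable(
        acidic={str(k): float(v) for k, v in data["acidic"].items()},
        basic={str(k): float(v) for k, v in data["basic"].items()},
        n_terminus=float(data["n_terminus"]),
        c_terminus=float(data["c_terminus"]),
        name=str(data.get("name", "")),
    )


def load_hydrophobicity_scale(source: str | Path | None = None) -> HydrophobicityScale:
    """Load a hydrophobicity scale (default: Kyte–Doolittle, mean mode)."""
    data = _load_yaml(source, "kyte_doolittle.yaml")
    return HydrophobicityScale(
        values={str(k): float(v) for k, v in data["values"].items()},
        aggregation=str(data.get("aggregation", "mean")),
        name=str(data.get("name", "")),
    )


def _check_sequence(seq: str) -> str:
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    for i, aa in enumerate(seq, start=1):
        if aa not in AMINO_ACIDS:
            raise UnknownResidueError(f"unknown residue {aa!r} at position {i}")
    return seq


def segment_charge(
    seq: str,
    pH: float = 8.0,
    pka: PkaTable | None = None,
    include_termini: bool = False,
) -> float:
    """Net charge of a peptide at `pH` in elementary-charge units."""
    if not 0.0 < pH < 14.0:
        raise ValueError(f"pH out of (0, 14): {pH}")
    seq = _check_sequence(seq)
    if pka is None:
        pka = load_pka_table()
    counts = {aa: seq.count(aa) for aa in set(seq)}
    charge = 0.0
    for aa, n in counts.items():
        if aa in pka.basic:
            charge += n / (1.0 + 10.0 ** (pH - pka.basic[aa]))
        elif aa in pka.acidic:
            charge -= n / (1.0 + 10.0 ** (pka.acidic[aa] - pH))
    if include_termini:
        charge += 1.0 / (1.0 + 10.0 ** (pH - pka.n_terminus))
        charge -= 1.0 / (1.0 + 10.0 ** (pka.c_terminus - pH))
    return charge


def segment_hydrophobicity(seq: str, scale: HydrophobicityScale | None = None) -> float:
    """Aggregate per-residue hydrophobicity (mean mode = GRAVY)."""
    seq = _check_sequence(seq)
    if scale is None:
        scale = load_hydrophobicity_scale()
    values = np.array([scale.values[aa] for aa in seq], dtype=float)
    return float(values.mean() if scale.aggregation == "mean" else values.sum())


def tabulate_allele_properties(
    scheme: ClassificationScheme | None = None,
    reference: OmpAReference | None = None,
    pH: float = 8.0,
    pka: PkaTable | None = None,
    scale: HydrophobicityScale | None = None,
    alleles: tuple[tuple[str, str], ...] = EXEMPLAR_ALLELES,
) -> pd.DataFrame:
    """Per-allele, per-loop charge and hydrophobicity matrix.

    Rows are the surface loops plus subtotal rows for the N-terminal loops
    (1–4), the C-terminal loops (5–8, 16-strand model), and all exposed
    loops. Columns are a two-level index (property, allele label). Alleles
    sharing identical sequences over a segment share its value exactly, so
    every C-terminal loop row is constant across alleles whose patterns only
    edit positions 175/203/251.
    """
    if reference is None:
        reference = load_reference()
    if scheme is None:
        scheme = load_scheme(reference=reference)
    if pka is None:
        pka = load_pka_table()
    if scale is None:
        scale = load_hydrophobicity_scale()
    loops = [seg for seg in reference.segments if seg.surface_exposed]
    for seg in loops:
        if seg.end > len(reference.mature_sequence):
            raise ValueError(f"segment {seg.name} outside sequence bounds")
    columns: dict[tuple[str, str], dict[str, float]] = {}
    for nterm, cterm in alleles:
        label = f"({nterm}, {cterm})"
        seq = build_allele_sequence(nterm, cterm, scheme, reference)
        # loop-length edits keep everything downstream aligned only if the
        # sequence is re-sliced per-allele through cumulative offsets; we
        # rebuild coordinates by re-anchoring each loop on the edited chain.
        charges: dict[str, float] = {}
        hydro: dict[str, float] = {}
        offset = 0  # cumulative length drift from loop-run edits upstream
        for seg in sorted(reference.segments, key=lambda s: s.start):
            drift = _segment_length_drift(seg, nterm, scheme)
            start = seg.start + offset
            end = seg.end + offset + drift
            sub = seq[start - 1 : end]
            offset += drift
            if seg.surface_exposed:
                charges[seg.name] = segment_charge(sub, pH=pH, pka=pka, include_termini=False)
                hydro[seg.name] = segment_hydrophobicity(sub, scale=scale)
        charges["sum_nterm_loops"] = sum(charges[n] for n in N_TERMINAL_LOOPS)
        charges["sum_cterm_loops"] = sum(charges[n] for n in C_TERMINAL_LOOPS)
        charges["sum_all_loops"] = charges["sum_nterm_loops"] + charges["sum_cterm_loops"]
        hydro["sum_nterm_loops"] = sum(hydro[n] for n in N_TERMINAL_LOOPS)
        hydro["sum_cterm_loops"] = sum(hydro[n] for n in C_TERMINAL_LOOPS)
        hydro["sum_all_loops"] = hydro["sum_nterm_loops"] + hydro["sum_cterm_loops"]
        columns[("charge", label)] = charges
        columns[("hydrophobicity", label)] = hydro
    table = pd.DataFrame(columns)
    row_order = [*N_TERMINAL_LOOPS, "sum_nterm_loops", *C_TERMINAL_LOOPS,
                 "sum_cterm_loops", "sum_all_loops"]
    return table.loc[row_order]


def _segment_length_drift(seg, nterm: str, scheme: ClassificationScheme) -> int:
    """Net length change a pattern's loop-run edits cause inside `seg`."""
    drift = 0
    for site in scheme.nterm_sites:
        if seg.start <= site.start and site.end <= seg.end:
            drift += len(scheme.nterm_patterns[nterm][site.name]) - (site.end - site.start + 1)
    return drift


def correlate_predictions_with_measurements(
    predicted: dict[str, float] | pd.Series,
    measured: dict[str, float] | pd.Series,
    conf: float = 0.95,
):
    """Regress measured per-allele means on predicted per-allele sums and
    judge the association by whether the slope CI spans zero (delegates to
    :func:`ompakit.stats.slope_ci_association`)."""
    from .stats import slope_ci_association

    predicted = pd.Series(predicted)
    measured = pd.Series(measured)
    common = predicted.index.intersection(measured.index)
    if len(common) < 3:
        raise ValueError("need at least 3 alleles with both predicted and measured values")
    return slope_ci_association(
        predicted.loc[common].to_numpy(), measured.loc[common].to_numpy(), conf=conf
    )
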