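"""Synthetic-data generators with known ground truth.

Every pipeline stage can be exercised without downloads: near-identical OmpA
protein sequences planted with defined alleles (including the loop-3 length
polymorphism and optional indels), Gaussian replicate phenotypes with
allele-level means, lag/exponential/plateau OD550 curves with multiplicative
noise, and multinomial allele-count tables with planted enrichments.

The defaults emulate the study conditions: seven exemplar alleles in one
genetic background, a 10-fold biofilm separation between the alpha and the
beta/gamma C-terminal groups, 15-hour growth curves sampled every 10 minutes,
and cohort sizes of 78 environmental vs 412 ExPEC isolates.

All generators are pure functions of (config, seed). A single seed feeds a
hierarchical stream split (one spawned child per generator), so adding a call
to one generator never perturbs another's draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alleles import ClassificationScheme, build_allele_sequence, load_scheme
from .growth import GrowthCurve
from .reference import AMINO_ACIDS, OmpAReference, load_reference
from .stats import CountTable

EXEMPLAR_ALLELES = (
    ("I", "alpha"),
    ("II", "alpha"),
    ("III", "gamma"),
    ("IV", "beta"),
    ("V", "alpha"),
    ("VI", "alpha"),
    ("VII", "beta"),
)

_STREAM = {"sequences": 0, "phenotypes": 1, "growth": 2, "counts": 3}


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs for all generators; defaults are the study-like conditions."""

    # sequences
    alleles: tuple[tuple[str, str], ...] = EXEMPLAR_ALLELES
    sequences_per_allele: int = 15
    mutation_rate: float = 0.0        # per non-site position
    loop3_indel_prob: float = 0.0     # per sequence, one-residue loop-3 indel
    site_noise_rate: float = 0.0      # per classification site, novel-forcing
    # phenotypes
    replicates: int = 6
    phenotype_means: dict = field(default_factory=dict)   # phenotype -> {label: (mean, sd)}
    # growth
    n_curves: int = 20
    mu: float = 0.6                   # 1/h
    lag_hours: float = 1.0
    breakpoint_hours: float = 6.0     # end of exponential phase
    total_hours: float = 15.0
    sampling_minutes: float = 10.0
    od0: float = 0.05
    growth_noise_sd: float = 0.01     # multiplicative
    # counts
    group_sizes: dict = field(default_factory=lambda: {"environmental": 78, "ExPEC": 412})
    allele_frequencies: dict = field(default_factory=dict)  # group -> {allele: freq}
    planted_odds: dict = field(default_factory=dict)        # (group, allele) -> odds multiplier


def _rng(seed: int, stream: str) -> np.random.Generator:
    child = np.random.SeedSequence(seed).spawn(max(_STREAM.values()) + 1)[_STREAM[stream]]
    return np.random.default_rng(child)


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------

def _protected_positions(scheme: ClassificationScheme, nterm: str) -> set[int]:
    """Positions (1-based, on the allele's own edited chain) that background
    mutations must avoid: classification sites plus run flanking anchors."""
    protected: set[int] = set()
    for s in scheme.nterm_sites:
        off = _offset_at(scheme, nterm, s.start)
        run_len = len(scheme.nterm_patterns[nterm][s.name])
        protected.update(range(s.start - 1 + off, s.start + run_len + 1 + off))
    for p in scheme.cterm_sites:
        protected.add(p + _offset_at(scheme, nterm, p))
    return protected


def _offset_at(scheme: ClassificationScheme, nterm: str, pos: int) -> int:
    """Length drift accumulated before reference position `pos` by the
    pattern's loop-run edits (e.g. +1 downstream of an 8-residue loop 3)."""
    off = 0
    for s in scheme.nterm_sites:
        if s.end < pos:
            off += len(scheme.nterm_patterns[nterm][s.name]) - (s.end - s.start + 1)
    return off


def _novel_run(run: str, forbidden: set[str], rng: np.random.Generator) -> str:
    """Substitute one residue so the run matches no pattern exactly."""
    choices = sorted(AMINO_ACIDS)
    for _ in range(50):
        i = int(rng.integers(len(run)))
        aa = choices[int(rng.integers(len(choices)))]
        cand = run[:i] + aa + run[i + 1 :]
        if cand != run and cand not in forbidden:
            return cand
    raise RuntimeError("could not construct a novel site value")


def gen_sequences(
    config: SimulationConfig,
    seed: int,
    scheme: ClassificationScheme | None = None,
    reference: OmpAReference | None = None,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Generate planted-allele protein sequences and their truth table.

    Returns ``(records, truth)`` where `records` is a list of
    ``(id, sequence)`` in deterministic order and `truth` records the
    intended allele and any perturbations per record. Background mutations
    avoid classification sites (and their flanking anchor positions) unless
    `site_noise_rate` plants novel-forcing site mutations, whose presence is
    recorded in the truth table.
    """
    if reference is None:
        reference = load_reference()
    if scheme is None:
        scheme = load_scheme(reference=reference)
    rng = _rng(seed, "sequences")
    loop3 = reference.segment("loop3")
    loop3_site = scheme.nterm_site("loop3")
    # indel positions: inside loop 3, at least two residues clear of the run
    # site and its anchors so the alignment optimum around the run is unique
    indel_positions = [
        p for p in range(loop3.start, loop3.end + 1)
        if p < loop3_site.start - 1 or p > loop3_site.end + 2
    ]
    choices = sorted(AMINO_ACIDS)
    records: list[tuple[str, str]] = []
    truth_rows = []
    for nterm, cterm in config.alleles:
        base = build_allele_sequence(nterm, cterm, scheme, reference)
        protected = _protected_positions(scheme, nterm)
        for k in range(config.sequences_per_allele):
            seq = list(base)
            n_background = 0
            site_mutated = []
            if config.mutation_rate > 0:
                for pos in range(1, len(base) + 1):
                    if pos in protected:
                        continue
                    if rng.random() < config.mutation_rate:
                        current = seq[pos - 1]
                        aa = choices[int(rng.integers(len(choices)))]
                        if aa != current:
                            seq[pos - 1] = aa
                            n_background += 1
            if config.site_noise_rate > 0:
                seq_str = "".join(seq)
                for site in scheme.nterm_sites:
                    if rng.random() < config.site_noise_rate:
                        forbidden = {pat[site.name] for pat in scheme.nterm_patterns.values()}
                        run = scheme.nterm_patterns[nterm][site.name]
                        idx = site.start - 1 + _offset_at(scheme, nterm, site.start)
                        assert seq_str[idx : idx + len(run)] == run
                        novel = _novel_run(run, forbidden, rng)
                        seq_str = seq_str[:idx] + novel + seq_str[idx + len(run) :]
                        site_mutated.append(site.name)
                for pos in scheme.cterm_sites:
                    if rng.random() < config.site_noise_rate:
                        forbidden = {pat[pos] for pat in scheme.cterm_patterns.values()}
                        idx = pos - 1 + _offset_at(scheme, nterm, pos)
                        novel = _novel_run(seq_str[idx], forbidden, rng)
                        seq_str = seq_str[:idx] + novel + seq_str[idx + 1 :]
                        site_mutated.append(f"pos{pos}")
                seq = list(seq_str)
            indel = ""
            if config.loop3_indel_prob > 0 and rng.random() < config.loop3_indel_prob:
                pos = int(rng.choice(indel_positions))
                idx = pos - 1 + _offset_at(scheme, nterm, pos)
                if rng.random() < 0.5:
                    seq.insert(idx, seq[idx])  # duplicate one residue
                    indel = f"ins@{pos}"
                else:
                    del seq[idx]
                    indel = f"del@{pos}"
            rec_id = f"syn_{nterm}_{cterm}_{k:03d}"
            records.append((rec_id, "".join(seq)))
            truth_rows.append(
                {
                    "id": rec_id,
                    "nterm": nterm,
                    "cterm": cterm,
                    "n_background_mutations": n_background,
                    "sites_mutated": ";".join(site_mutated),
                    "loop3_indel": indel,
                }
            )
    return records, pd.DataFrame(truth_rows)


def records_to_fasta(records: list[tuple[str, str]]) -> str:
    lines = []
    for rec_id, seq in records:
        lines.append(f">{rec_id}")
        lines.extend(seq[i : i + 60] for i in range(0, len(seq), 60))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def fig2_biofilm_preset(high: float = 2.0, fold: float = 10.0, cv: float = 0.15) -> dict:
    """Biofilm means with the 10-fold separation between alpha alleles and
    the beta/gamma alleles, relative SD `cv`."""
    means = {}
    for nterm, cterm in EXEMPLAR_ALLELES:
        mean = high if cterm == "alpha" else high / fold
        means[f"({nterm}, {cterm})"] = (mean, cv * mean)
    return {"biofilm": means}


def gen_phenotypes(config: SimulationConfig, seed: int) -> pd.DataFrame:
    """Gaussian replicate draws around per-allele means.

    Returns a long-format table ``strain,allele,phenotype,replicate,value``.
    `config.phenotype_means` maps phenotype name -> {allele label: (mean, sd)};
    when empty, the 10-fold biofilm preset is used.
    """
    rng = _rng(seed, "phenotypes")
    phenotype_means = config.phenotype_means or fig2_biofilm_preset()
    rows = []
    for phenotype, by_allele in phenotype_means.items():
        for label, (mean, sd) in by_allele.items():
            values = mean + sd * rng.standard_normal(config.replicates)
            for r, v in enumerate(values, start=1):
                rows.append(
                    {
                        "strain": f"MG1655d_{label}",
                        "allele": label,
                        "phenotype": phenotype,
                        "replicate": r,
                        "value": float(v),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Growth curves
# ---------------------------------------------------------------------------

def gen_growth_curves(config: SimulationConfig, seed: int) -> tuple[list[GrowthCurve], pd.DataFrame]:
    """Piecewise lag/exponential/plateau OD550 curves with multiplicative
    Gaussian noise; the truth table records mu and the breakpoint index."""
    rng = _rng(seed, "growth")
    dt = config.sampling_minutes / 60.0
    times = np.arange(0.0, config.total_hours + 1e-9, dt)
    curves, rows = [], []
    for i in range(config.n_curves):
        t_eff = np.clip(times - config.lag_hours, 0.0, config.breakpoint_hours - config.lag_hours)
        od = config.od0 * np.exp(config.mu * t_eff)
        noisy = od * (1.0 + config.growth_noise_sd * rng.standard_normal(times.size))
        noisy = np.maximum(noisy, 1e-6)
        curves.append(GrowthCurve(times=times, od=noisy, strain=f"sim_{i:03d}"))
        rows.append(
            {
                "strain": f"sim_{i:03d}",
                "mu": config.mu,
                "lag_index": int(np.searchsorted(times, config.lag_hours)),
                "breakpoint_index": int(np.searchsorted(times, config.breakpoint_hours)),
            }
        )
    return curves, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Count tables
# ---------------------------------------------------------------------------

def gen_count_table(config: SimulationConfig, seed: int) -> tuple[CountTable, pd.DataFrame]:
    """Multinomial allele counts per group with planted enrichment odds.

    Frequencies default to uniform over the seven exemplar labels; a
    ``(group, allele) -> odds`` entry multiplies that cell's frequency before
    renormalization. The truth table records the planted cells.
    """
    rng = _rng(seed, "counts")
    labels = [f"({n}, {c})" for n, c in EXEMPLAR_ALLELES]
    groups = list(config.group_sizes)
    base = {g: dict(config.allele_frequencies.get(g, {l: 1.0 / len(labels) for l in labels}))
            for g in groups}
    truth_rows = []
    counts = {}
    for g in groups:
        freqs = dict(base[g])
        total = sum(freqs.values())
        freqs = {a: f / total for a, f in freqs.items()}
        for (pg, pa), odds in config.planted_odds.items():
            if pg == g:
                freqs[pa] = freqs.get(pa, 0.0) * odds
                truth_rows.append({"group": g, "allele": pa, "odds": odds})
        total = sum(freqs.values())
        probs = np.array([freqs[a] / total for a in sorted(freqs)])
        draw = rng.multinomial(config.group_sizes[g], probs)
        counts[g] = dict(zip(sorted(freqs), draw.tolist()))
    df = pd.DataFrame(counts).T.fillna(0).astype(int)
    table = CountTable(counts=df, group_sizes=pd.Series(config.group_sizes), reconstructed=False)
    return table, pd.DataFrame(truth_rows, columns=["group", "allele", "odds"])
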