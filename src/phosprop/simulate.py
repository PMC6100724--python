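"""Seeded synthetic data: toy proteomes, selection truths, and FASTQ pools.

Phage selection is modeled as enrichment-weight exponentiation: after t
rounds, entry e is sampled with probability proportional to
``pi_e * lambda_e ** t`` where pi_e is its naive-library frequency and
lambda_e its per-round enrichment weight.  Reads are drawn multinomially
at a fixed depth, formatted as barcode + 5' flank + insert + 3' flank,
with i.i.d. substitution errors downstream of the barcode and Phred
strings from a truncated-normal quality profile.  All randomness flows
from one integer seed; identical seed and configuration give
byte-identical FASTQ.

This deliberately omits PCR bias, indels, chimeras, and phage growth
dynamics — it exists to exercise the deconvolution and scoring stages
against a known ground truth, not to model sequencer physics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .design import (
    CLASS_I, CLASS_II, CLASS_III, CLASS_NONE, DesignConfig, LibraryEntry,
    CTermPeptide, PhosphositeAnnotation, ProteinRecord, build_design,
)
from .ngs import SampleRow, SampleSheet


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------- toy proteome

@dataclass(frozen=True)
class PlanItem:
    """How many C-termini of one PDZbm class, with phosphosites where."""

    pdzbm_class: str  # classI / classII / classIII / none
    site_positions: tuple[int, ...]  # p-indices carrying annotated S/T sites
    n: int = 1


#: residues that never collide with class-defining positions
_NEUTRAL = "GNQHKRP"
_PHI = "AVILMFWYC"


def _cterm_for(item: PlanItem, rng: np.random.Generator, L: int) -> str:
    """One C-terminal L-mer satisfying the planned class and sites."""
    chars = [_NEUTRAL[i] for i in rng.integers(0, len(_NEUTRAL), L)]

    def setpos(p: int, c: str) -> None:
        chars[L - 1 + p] = c

    cls = item.pdzbm_class
    if cls in (CLASS_I, CLASS_II, CLASS_III):
        setpos(0, _PHI[rng.integers(0, len(_PHI))])
    else:
        setpos(0, "G")
    if cls == CLASS_I:
        setpos(-2, "ST"[rng.integers(0, 2)])
    elif cls == CLASS_II:
        setpos(-2, _PHI[rng.integers(0, len(_PHI))])
    elif cls == CLASS_III:
        setpos(-2, "DE"[rng.integers(0, 2)])
    for p in item.site_positions:
        if not -(L - 1) <= p <= 0:
            raise SimulationError(f"site p-index {p} outside peptide of length {L}")
        want = "ST"[rng.integers(0, 2)]
        if p == 0 and cls != CLASS_NONE:
            raise SimulationError(f"class {cls} needs hydrophobic p0; site at p0 infeasible")
        if p == -2:
            if cls in (CLASS_II, CLASS_III):
                raise SimulationError(f"class {cls} at p-2 conflicts with an S/T site there")
            setpos(-2, chars[L - 3] if cls == CLASS_I else want)
        else:
            setpos(p, want)
    return "".join(chars)


def make_toy_proteome(
    plan: list[PlanItem],
    seed: int,
    L: int = 9,
    min_len: int = 20,
    max_len: int = 40,
) -> tuple[list[ProteinRecord], list[PhosphositeAnnotation]]:
    """Deterministic toy proteome whose C-termini realize a motif plan.

    Each plan item yields ``n`` proteins with distinct C-terminal L-mers
    of the requested PDZbm class, with annotated S/T phosphosites at the
    requested p-indices.  The planted composition is exactly recoverable
    by motif classification of the resulting design.
    """
    rng = np.random.default_rng(seed)
    seen: set[str] = set()
    proteins, annotations = [], []
    idx = 0
    for item in plan:
        for _ in range(item.n):
            for _attempt in range(1000):
                cterm = _cterm_for(item, rng, L)
                if cterm not in seen:
                    break
            else:
                raise SimulationError("could not generate enough unique C-termini")
            seen.add(cterm)
            idx += 1
            n_res = int(rng.integers(min_len, max_len + 1))
            body = "".join(_NEUTRAL[i] for i in rng.integers(0, len(_NEUTRAL), n_res - L))
            seq = body + cterm
            pid = f"SYN{idx:04d}"
            proteins.append(ProteinRecord(protein_id=pid, sequence=seq))
            for p in item.site_positions:
                annotations.append(PhosphositeAnnotation(
                    protein_id=pid, position=len(seq) + p, residue=seq[len(seq) - 1 + p],
                    source="synthetic",
                ))
    return proteins, annotations


def write_proteome(proteins: list[ProteinRecord],
                   annotations: list[PhosphositeAnnotation],
                   fasta_path: str | Path, sites_path: str | Path) -> None:
    with open(fasta_path, "w") as fh:
        for p in proteins:
            fh.write(f">{p.protein_id}\n{p.sequence}\n")
    import pandas as pd

    pd.DataFrame([{
        "protein_id": a.protein_id, "position": a.position, "residue": a.residue,
        "source": a.source, "kinase": a.kinase or "",
    } for a in annotations]).to_csv(sites_path, sep="\t", index=False)


# ---------------------------------------------------------------- selection model

@dataclass
class SelectionTruth:
    """Ground-truth enrichment model behind a simulated selection."""

    lambdas: dict[str, float]  # per-entry per-round enrichment weight
    rounds: int = 3
    naive_freq: dict[str, float] | None = None  # pi_e; None = uniform
    depth: int = 50_000
    error_rate: float = 0.002
    qual_mean: float = 35.0
    qual_sd: float = 3.0
    seed: int = 0
    #: per-condition lambda overrides (e.g. a pre-phosphorylated pool)
    condition_lambdas: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise SimulationError("sequencing depth must be >= 1")
        if any(l <= 0 for l in self.lambdas.values()):
            raise SimulationError("enrichment weights must be positive")

    def expected_fractions(self, condition: str = "selection") -> dict[str, float]:
        """Sampling probabilities pi * lambda^t, normalized; t=0 for naive."""
        ids = sorted(self.lambdas)
        pi = (np.full(len(ids), 1.0 / len(ids)) if self.naive_freq is None
              else np.array([self.naive_freq[e] for e in ids]))
        t = 0 if condition == "naive" else self.rounds
        lam = self.condition_lambdas.get(condition, self.lambdas)
        w = pi * np.array([lam[e] for e in ids]) ** t
        w = w / w.sum()
        return dict(zip(ids, w))

    def expected_pair_score(self, wt_entry: str, mim_entry: str,
                            condition: str = "selection") -> float:
        f = self.expected_fractions(condition)
        w, m = f[wt_entry], f[mim_entry]
        return m / (w + m)


def _mutate(seq: str, n_err: int, rng: np.random.Generator) -> str:
    if n_err == 0:
        return seq
    pos = rng.choice(len(seq), size=min(n_err, len(seq)), replace=False)
    chars = list(seq)
    for i in pos:
        alts = [b for b in "ACGT" if b != chars[i]]
        chars[i] = alts[rng.integers(0, 3)]
    return "".join(chars)


def simulate_selection(
    design: list[LibraryEntry],
    truth: SelectionTruth,
    samplesheet: SampleSheet,
    out_dir: str | Path,
    config: DesignConfig = DesignConfig(),
) -> dict[str, Path]:
    """Write one FASTQ per sample drawn from the truth model.

    Reads are ``fwd_barcode + flank5 + nt_seq + flank3``; substitution
    errors (rate ``error_rate``) apply downstream of the barcode so that
    demultiplexing is exact.  A ``ground_truth.tsv`` of expected per-entry
    fractions per sample is written alongside.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    by_id = {e.entry_id: e for e in design}
    missing = set(truth.lambdas) - set(by_id)
    if missing:
        raise SimulationError(f"truth weights for unknown entries: {sorted(missing)[:3]}")
    paths: dict[str, Path] = {}
    truth_rows = []
    for si, row in enumerate(samplesheet.rows):
        rng = np.random.default_rng([truth.seed, si])
        probs = truth.expected_fractions(row.condition)
        ids = sorted(probs)
        counts = rng.multinomial(truth.depth, [probs[e] for e in ids])
        path = out_dir / f"{row.sample_id}.fastq"
        tail_len = len(config.flank5) + len(design[0].nt_seq) + len(config.flank3)
        with open(path, "w") as fh:
            ridx = 0
            for eid, c in zip(ids, counts):
                truth_rows.append({"sample_id": row.sample_id, "entry_id": eid,
                                   "expected_fraction": probs[eid], "drawn_count": int(c)})
                if c == 0:
                    continue
                tail0 = config.flank5 + by_id[eid].nt_seq + config.flank3
                n_errs = rng.binomial(tail_len, truth.error_rate, size=c)
                quals = np.clip(np.rint(rng.normal(truth.qual_mean, truth.qual_sd,
                                                   size=(c, len(row.fwd_barcode) + tail_len))),
                                2, 41).astype(int)
                for j in range(c):
                    ridx += 1
                    seq = row.fwd_barcode + _mutate(tail0, int(n_errs[j]), rng)
                    qual = "".join(chr(q + 33) for q in quals[j])
                    fh.write(f"@{row.sample_id}_{ridx}\n{seq}\n+\n{qual}\n")
        paths[row.sample_id] = path
    import pandas as pd

    pd.DataFrame(truth_rows).to_csv(out_dir / "ground_truth.tsv", sep="\t", index=False)
    return paths


# ---------------------------------------------------------------- scenarios

SCENARIOS = ("neutral", "p2_disable", "p3_enable", "pre_phospho_shift", "mixed")

_BARCODE_ALPHA = "ACGT"


def _barcodes(n: int, length: int, rng: np.random.Generator) -> list[str]:
    out: set[str] = set()
    while len(out) < n:
        out.add("".join(_BARCODE_ALPHA[i] for i in rng.integers(0, 4, length)))
    return sorted(out)


@dataclass
class Fixture:
    """A complete simulated experiment plus machine-readable expectations."""

    proteome: list[ProteinRecord]
    annotations: list[PhosphositeAnnotation]
    design: list[LibraryEntry]
    samplesheet: SampleSheet
    truth: SelectionTruth
    fastq: dict[str, Path]
    config: DesignConfig
    expectations: dict


def _scenario_lambdas(scenario: str, design: list[LibraryEntry],
                      ratio: float) -> tuple[dict[str, float], dict]:
    """Per-entry weights planting the scenario's switches.

    p-2 sites are planted disabling (wild type enriched ``ratio`` times
    stronger per round than the mimetic), p-3 sites enabling, all other
    sites neutral; the neutral scenario plants nothing.
    """
    lam = {e.entry_id: 1.0 for e in design}
    expect: dict = {"enabling_sites": [], "disabling_sites": [], "neutral_sites": []}
    for e in design:
        sites = e.peptide.site_positions
        if len(sites) != 1:
            continue
        site = next(iter(sites))
        if e.is_wild_type:
            continue
        if scenario in ("p2_disable", "mixed") and site == -2:
            lam[e.entry_id] = 1.0 / ratio
            expect["disabling_sites"].append(site)
        elif scenario in ("p3_enable", "mixed") and site == -3:
            lam[e.entry_id] = ratio
            expect["enabling_sites"].append(site)
        else:
            expect["neutral_sites"].append(site)
    for key in ("enabling_sites", "disabling_sites", "neutral_sites"):
        expect[key] = sorted(set(expect[key]))
    return lam, expect


def end_to_end_fixture(
    scenario: str,
    seed: int,
    out_dir: str | Path,
    depth: int = 50_000,
    replicates: int = 3,
    rounds: int = 3,
    lambda_ratio: float = 4.0,
    peptides_per_group: int = 6,
    error_rate: float = 0.002,
) -> Fixture:
    """Build inputs + expected outputs for one named scenario.

    Scenarios: ``neutral`` (no switches), ``p2_disable``, ``p3_enable``,
    ``mixed`` (both, plus neutral positions), ``pre_phospho_shift`` (two
    conditions, one wild-type entry enriched threefold in the second).
    """
    if scenario not in SCENARIOS:
        raise SimulationError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    rng = np.random.default_rng([seed, 7])
    plan = [
        PlanItem(CLASS_I, (-2,), peptides_per_group),
        PlanItem(CLASS_I, (-3,), peptides_per_group),
        PlanItem(CLASS_I, (-5,), peptides_per_group),
        PlanItem(CLASS_II, (-4,), max(peptides_per_group // 2, 1)),
        PlanItem(CLASS_NONE, (-1,), max(peptides_per_group // 2, 1)),
    ]
    proteome, annotations = make_toy_proteome(plan, seed=seed)
    config = DesignConfig()
    design = build_design(proteome, annotations, config)

    lam, expect = _scenario_lambdas(scenario, design, lambda_ratio)
    conditions = ["selection"]
    condition_lambdas: dict[str, dict[str, float]] = {}
    if scenario == "pre_phospho_shift":
        conditions = ["selection", "pre_phospho"]
        # one wild-type entry enriched 3x (per fold of expected fractions)
        wt_ids = sorted(e.entry_id for e in design if e.is_wild_type)
        planted = wt_ids[0]
        lam2 = dict(lam)
        lam2[planted] = lam[planted] * 3.0 ** (1.0 / rounds)
        condition_lambdas["pre_phospho"] = lam2
        expect["planted_entry"] = planted

    bait = "PDZ1"
    n_samples = replicates * len(conditions)
    fwd = _barcodes(n_samples, 8, rng)
    rev = _barcodes(n_samples, 6, rng)
    rows, i = [], 0
    for cond in conditions:
        for rep in range(1, replicates + 1):
            rows.append(SampleRow(f"{bait}_{cond}_r{rep}", fwd[i], rev[i], bait, rep, cond))
            i += 1
    samplesheet = SampleSheet(rows)

    truth = SelectionTruth(lambdas=lam, rounds=rounds, depth=depth,
                           error_rate=error_rate, seed=seed,
                           condition_lambdas=condition_lambdas)
    fastq = simulate_selection(design, truth, samplesheet, out_dir, config)

    # expected pair scores / folds straight from the truth model
    exp_scores = {}
    for e in design:
        if e.is_wild_type or len(e.peptide.site_positions) != 1:
            continue
        site = next(iter(e.peptide.site_positions))
        wt_id = f"{e.peptide.peptide_id}:wt"
        exp_scores[(e.peptide.peptide_id, site)] = truth.expected_pair_score(wt_id, e.entry_id)
    expect["expected_pair_scores"] = exp_scores
    if scenario == "pre_phospho_shift":
        fa = truth.expected_fractions("pre_phospho")
        fb = truth.expected_fractions("selection")
        expect["expected_fold"] = fa[expect["planted_entry"]] / fb[expect["planted_entry"]]

    return Fixture(proteome=proteome, annotations=annotations, design=design,
                   samplesheet=samplesheet, truth=truth, fastq=fastq,
                   config=config, expectations=expect)


def random_nt_entries(n: int, length: int, seed: int) -> list[LibraryEntry]:
    """n distinct random nucleotide inserts wrapped as index-ready entries.

    For stress-testing the mismatch index; the peptide attached to each
    entry is a placeholder and the inserts need not be translatable.
    """
    rng = np.random.default_rng(seed)
    seen: set[str] = set()
    while len(seen) < n:
        seen.add("".join("ACGT"[i] for i in rng.integers(0, 4, length)))
    pep = CTermPeptide(aa_seq="A" * 9, site_positions=frozenset([-2]),
                       source_proteins=frozenset(["SYN"]))
    return [
        LibraryEntry(entry_id=f"rnd{i:05d}", peptide=pep,
                     mimetic_mask=frozenset(), aa_seq=pep.aa_seq, nt_seq=nt)
        for i, nt in enumerate(sorted(seen))
    ]
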