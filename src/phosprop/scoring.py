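"""Scoring of phosphomimetic phage-selection outcomes.

Count tables are first converted to within-pool fractions (sequencing
depth differs between pools, so fractions — not raw counts — are the
comparable quantity).  For every single-phosphosite peptide the wild-type
and phosphomimetic variants form a pair, and the pair score in replicate r
is

    s_r = m_r / (w_r + m_r)

with w_r, m_r the wild-type and mimetic fractions.  s = 0 means the
selection was dominated by the wild type (the phosphomimetic mutation
disables binding); s = 1 means mimetic domination (enabling).  Scores are
aggregated per C-anchored position into a position score matrix, tested
against the neutral value 0.5 with a one-sample t-test across replicates
and Benjamini-Hochberg control at FDR 2.5%.

Also here: position weight matrices with per-column information content,
condition comparisons, naive-library representation-bias checks, affinity
arithmetic (K_D fold changes and ΔΔG), and kinase-category enrichment by
one-sided Fisher tests with Holm correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .design import CLASS_NONE, DEFAULT_PHI, LibraryEntry, classify_pdzbm, mask_to_str
from .ngs import CountTable, SampleSheet

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")
#: gas constant in kcal/(mol*K)
R_KCAL = 1.98720425e-3


class ScoringError(ValueError):
    pass


# ---------------------------------------------------------------- fractions

@dataclass
class FractionTable:
    """Per-pool count fractions with replicate metadata attached."""

    frame: pd.DataFrame  # sample_id, entry_id, fraction
    totals: dict[str, int]
    samplesheet: SampleSheet | None = None

    def fraction(self, sample_id: str, entry_id: str) -> float:
        sel = self.frame[(self.frame.sample_id == sample_id) & (self.frame.entry_id == entry_id)]
        return float(sel.fraction.iloc[0]) if len(sel) else 0.0

    def sample_map(self, sample_id: str) -> dict[str, float]:
        sel = self.frame[self.frame.sample_id == sample_id]
        return dict(zip(sel.entry_id, sel.fraction))


def normalize_fractions(counts: CountTable) -> FractionTable:
    """f = c / pool total, per sample; errors on an empty pool."""
    rows = []
    totals = {}
    sample_ids = sorted(counts.reads_in) if counts.reads_in else sorted({s for s, _ in counts.counts})
    for sid in sample_ids:
        if sid == "_undetermined":
            continue
        total = counts.sample_total(sid)
        if total == 0:
            raise ScoringError(f"sample {sid}: zero mapped reads, cannot normalize")
        totals[sid] = total
        for (s, e), c in counts.counts.items():
            if s == sid:
                rows.append({"sample_id": sid, "entry_id": e, "fraction": c / total})
    return FractionTable(pd.DataFrame(rows, columns=["sample_id", "entry_id", "fraction"]),
                         totals, counts.samplesheet)


def high_confidence_set(
    counts: CountTable,
    sample_id: str,
    min_count: int = 10,
    require_pdzbm: bool = True,
    design: Sequence[LibraryEntry] | None = None,
    phi_set: frozenset[str] = DEFAULT_PHI,
) -> set[str]:
    """Entries passing the per-pool count cutoff and, optionally, the motif filter."""
    keep = {e for (s, e), c in counts.counts.items() if s == sample_id and c >= min_count}
    if require_pdzbm:
        if design is None:
            raise ScoringError("require_pdzbm needs the design to classify motifs")
        by_id = {e.entry_id: e for e in design}
        keep = {e for e in keep
                if classify_pdzbm(by_id[e].aa_seq, phi_set) != CLASS_NONE}
    return keep


# ---------------------------------------------------------------- pair scores

@dataclass(frozen=True)
class PairScore:
    """Wild-type vs phosphomimetic pair for one single-site peptide."""

    bait: str
    peptide_id: str
    site: int  # p-index of the phosphosite
    replicates: tuple[int, ...]  # replicates contributing a score
    scores: tuple[float, ...]  # s_r, aligned with `replicates`
    f_wt: tuple[float, ...]  # wt fractions over ALL group replicates
    f_mim: tuple[float, ...]
    p_value: float  # two-sample t-test wt vs mimetic fractions
    significant: bool

    @property
    def mean(self) -> float:
        return float(np.mean(self.scores)) if self.scores else math.nan

    @property
    def sd(self) -> float:
        return float(np.std(self.scores, ddof=1)) if len(self.scores) > 1 else math.nan

    @property
    def n(self) -> int:
        return len(self.scores)


def replicate_samples(samplesheet: SampleSheet, bait: str, condition: str) -> list:
    rows = [r for r in samplesheet.rows if r.bait == bait and r.condition == condition]
    return sorted(rows, key=lambda r: r.replicate)


def _two_sample_p(a: Sequence[float], b: Sequence[float], welch: bool = False) -> float:
    if len(a) < 2 or len(b) < 2:
        return math.nan
    if np.std(a) == 0 and np.std(b) == 0:
        return math.nan if np.mean(a) != np.mean(b) else 1.0
    return float(stats.ttest_ind(a, b, equal_var=not welch).pvalue)


def pair_scores(
    fractions: FractionTable,
    design: Sequence[LibraryEntry],
    bait: str,
    condition: str = "selection",
    alpha: float = 0.05,
    welch: bool = False,
) -> list[PairScore]:
    """Score every single-site wt/mimetic pair for one bait's replicates.

    Multi-site peptides are excluded (their variants confound positions).
    A replicate contributes a score only when w_r + m_r > 0; a pair with
    no scoring replicate is dropped.  The pair p-value is a two-sided
    two-sample t-test of the wt vs mimetic fraction vectors across all
    replicates (equal-variance by default).
    """
    if fractions.samplesheet is None:
        raise ScoringError("fraction table carries no sample sheet")
    reps = replicate_samples(fractions.samplesheet, bait, condition)
    if not reps:
        raise ScoringError(f"no samples for bait {bait!r}, condition {condition!r}")
    maps = {r.sample_id: fractions.sample_map(r.sample_id) for r in reps}

    peptides = {}
    for e in design:
        if len(e.peptide.site_positions) == 1:
            peptides[e.peptide.peptide_id] = e.peptide
    out = []
    for pid, pep in sorted(peptides.items()):
        site = next(iter(pep.site_positions))
        wt_id = f"{pid}:wt"
        mim_id = f"{pid}:{mask_to_str(frozenset([site]))}"
        f_wt = tuple(maps[r.sample_id].get(wt_id, 0.0) for r in reps)
        f_mim = tuple(maps[r.sample_id].get(mim_id, 0.0) for r in reps)
        rep_ids, scores = [], []
        for r, w, m in zip(reps, f_wt, f_mim):
            if w + m > 0:
                rep_ids.append(r.replicate)
                scores.append(m / (w + m))
        if not scores:
            continue
        p = _two_sample_p(f_wt, f_mim, welch)
        out.append(PairScore(
            bait=bait, peptide_id=pid, site=site,
            replicates=tuple(rep_ids), scores=tuple(scores),
            f_wt=f_wt, f_mim=f_mim, p_value=p,
            significant=bool(p < alpha) if not math.isnan(p) else False,
        ))
    return out


def pair_scores_frame(pairs: Iterable[PairScore]) -> pd.DataFrame:
    rows = []
    for p in pairs:
        rows.append({
            "bait": p.bait, "peptide_id": p.peptide_id, "site": p.site,
            "mean_score": p.mean, "sd_score": p.sd, "n": p.n,
            "replicates": ",".join(map(str, p.replicates)),
            "scores": ",".join(f"{s:.6g}" for s in p.scores),
            "f_wt": ",".join(f"{v:.6g}" for v in p.f_wt),
            "f_mim": ",".join(f"{v:.6g}" for v in p.f_mim),
            "p_value": p.p_value, "significant": p.significant,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------- position matrix

def position_matrix(
    pairs: Iterable[PairScore],
    fdr: float = 0.025,
) -> pd.DataFrame:
    """Aggregate pair scores per (bait, p-index) and test against 0.5.

    Cell mean: equal-weight average of the pair-mean scores.  The p-value
    is a two-sided one-sample t-test of the per-replicate position means
    (mean score over contributing pairs, per replicate) against the
    neutral score 0.5.  Cells where every underlying observation is
    one-sided (only wild-type or only mimetic reads), or with fewer than
    two replicate means or zero variance, are flagged untestable.
    q-values are Benjamini-Hochberg within each bait over testable cells;
    a cell is called enabling/disabling when q <= fdr.
    """
    pairs = list(pairs)
    cells = []
    baits = sorted({p.bait for p in pairs})
    for bait in baits:
        bp = [p for p in pairs if p.bait == bait]
        for site in sorted({p.site for p in bp}):
            sp = [p for p in bp if p.site == site]
            mean_score = float(np.mean([p.mean for p in sp]))
            # per-replicate position means
            rep_scores: dict[int, list[float]] = {}
            for p in sp:
                for rid, s in zip(p.replicates, p.scores):
                    rep_scores.setdefault(rid, []).append(s)
            rep_means = [float(np.mean(v)) for _, v in sorted(rep_scores.items())]
            one_sided = (all(all(w == 0 for w in p.f_wt) for p in sp)
                         or all(all(m == 0 for m in p.f_mim) for p in sp))
            testable = (not one_sided and len(rep_means) >= 2
                        and float(np.std(rep_means)) > 0)
            pval = (float(stats.ttest_1samp(rep_means, 0.5).pvalue)
                    if testable else math.nan)
            cells.append({
                "bait": bait, "site": site, "mean_score": mean_score,
                "n_pairs": len(sp), "n_replicates": len(rep_means),
                "p_value": pval, "testable": testable,
            })
    df = pd.DataFrame(cells)
    if df.empty:
        return df.assign(q_value=[], significant=[], call=[])
    df["q_value"] = math.nan
    for bait in baits:
        mask = (df.bait == bait) & df.testable
        if mask.any():
            _, q, _, _ = multipletests(df.loc[mask, "p_value"], alpha=fdr, method="fdr_bh")
            df.loc[mask, "q_value"] = q
    df["significant"] = df.q_value.le(fdr) & df.testable
    df["call"] = "neutral"
    df.loc[df.significant & (df.mean_score > 0.5), "call"] = "enabling"
    df.loc[df.significant & (df.mean_score < 0.5), "call"] = "disabling"
    df.loc[~df.testable, "call"] = "untestable"
    return df


# ---------------------------------------------------------------- PWMs

@dataclass
class PWM:
    """Position probability matrix over C-anchored positions with column IC."""

    probs: pd.DataFrame  # index: p-index, columns: 20 amino acids
    ic: pd.Series  # bits per column
    n: int


def build_pwm(peptides: Sequence[str], weights: Sequence[float] | None = None) -> PWM:
    """Column frequencies and information content for C-anchored peptides.

    IC_j = log2(20) - H_j with H_j the Shannon entropy of column j in
    bits; no pseudocount or small-sample correction.  Weights (e.g. read
    counts) are optional; the default is one vote per peptide.
    """
    if not peptides:
        raise ScoringError("cannot build a PWM from zero peptides")
    L = len(peptides[0])
    if any(len(p) != L for p in peptides):
        raise ScoringError("peptides must share one length (C-anchored)")
    w = np.ones(len(peptides)) if weights is None else np.asarray(weights, float)
    if len(w) != len(peptides) or (w < 0).any() or w.sum() == 0:
        raise ScoringError("invalid weights")
    positions = list(range(-(L - 1), 1))
    mat = pd.DataFrame(0.0, index=positions, columns=list(AMINO_ACIDS))
    for pep, wt in zip(peptides, w):
        for j, aa in enumerate(pep):
            mat.loc[positions[j], aa] += wt
    probs = mat.div(mat.sum(axis=1), axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(probs.values > 0, probs.values * np.log2(probs.values), 0.0)
    entropy = -plogp.sum(axis=1)
    ic = pd.Series(math.log2(20) - entropy, index=positions, name="ic_bits")
    return PWM(probs=probs, ic=ic, n=len(peptides))


# ---------------------------------------------------------------- comparisons

def compare_selections(
    fractions_a: FractionTable,
    fractions_b: FractionTable,
    samples_a: Sequence[str],
    samples_b: Sequence[str],
    alpha: float = 0.05,
    welch: bool = False,
) -> pd.DataFrame:
    """Per-entry fraction fold (A over B) with replicate t-tests.

    fold = mean_A / mean_B; undefined (NaN, flagged) when mean_B is 0.
    """
    maps_a = [fractions_a.sample_map(s) for s in samples_a]
    maps_b = [fractions_b.sample_map(s) for s in samples_b]
    entries = sorted(set().union(*maps_a, *maps_b))
    rows = []
    for e in entries:
        va = [m.get(e, 0.0) for m in maps_a]
        vb = [m.get(e, 0.0) for m in maps_b]
        ma, mb = float(np.mean(va)), float(np.mean(vb))
        fold = ma / mb if mb > 0 else math.nan
        p = _two_sample_p(va, vb, welch)
        rows.append({
            "entry_id": e, "mean_a": ma, "mean_b": mb, "fold": fold,
            "fold_defined": mb > 0, "p_value": p,
            "significant": bool(p < alpha) if not math.isnan(p) else False,
        })
    return pd.DataFrame(rows)


def naive_bias_check(
    selection_counts: Mapping[str, int],
    naive_counts: Mapping[str, int],
    log_transform: bool = False,
) -> dict:
    """Representation-bias check of a selection against the naive library.

    Reports the Pearson correlation between the counts of selected
    entries and their naive-library counts (selection "strength" vs input
    representation), and a two-sample Mann-Whitney comparison of naive
    counts for selected vs unselected entries (detection sensitivity).
    Entries absent from the naive sequencing are not used.
    """
    naive_pos = {e: c for e, c in naive_counts.items() if c > 0}
    selected = [e for e in naive_pos if selection_counts.get(e, 0) > 0]
    if len(selected) < 3:
        raise ScoringError(f"need >= 3 selected entries with naive support, got {len(selected)}")
    x = np.array([selection_counts[e] for e in selected], float)
    y = np.array([naive_pos[e] for e in selected], float)
    if log_transform:
        x, y = np.log1p(x), np.log1p(y)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ScoringError("zero variance in counts: Pearson correlation undefined")
    r, p = stats.pearsonr(x, y)
    naive_sel = [naive_pos[e] for e in selected]
    naive_unsel = [c for e, c in naive_pos.items() if selection_counts.get(e, 0) == 0]
    if naive_unsel:
        u = stats.mannwhitneyu(naive_sel, naive_unsel, alternative="two-sided")
        det_p, det_stat = float(u.pvalue), float(u.statistic)
    else:
        det_p = det_stat = math.nan
    return {
        "pearson_r": float(r), "pearson_p": float(p), "n_selected": len(selected),
        "naive_median_selected": float(np.median(naive_sel)),
        "naive_median_unselected": float(np.median(naive_unsel)) if naive_unsel else math.nan,
        "detection_stat": det_stat, "detection_p": det_p,
    }


# ---------------------------------------------------------------- affinity

def fold_change(kd_a: float, kd_b: float) -> float:
    """K_D ratio a/b; pair with :func:`present_fold` for a printed 'N×'."""
    if kd_a <= 0 or kd_b <= 0:
        raise ScoringError("dissociation constants must be positive")
    return kd_a / kd_b


def present_fold(fold: float) -> str:
    return f"{round(fold):d}×"


def delta_delta_g(kd_phos: float, kd_unphos: float, temperature: float = 298.15) -> float:
    """ΔΔG = R·T·ln(K_D^phos / K_D^unphos) in kcal/mol (positive = weaker)."""
    if kd_phos <= 0 or kd_unphos <= 0 or temperature <= 0:
        raise ScoringError("K_D and temperature must be positive")
    return R_KCAL * temperature * math.log(kd_phos / kd_unphos)


def network_edges(pairs: Iterable[PairScore],
                  design: Sequence[LibraryEntry]) -> pd.DataFrame:
    """Bait-prey edge table with per-site switch calls.

    One row per scored wt/mimetic pair: bait domain, prey protein(s), the
    site's p-index, the call (enabling if the mimetic dominated and the
    pair test is significant, disabling if the wild type dominated,
    neutral otherwise), and the mean pair score.
    """
    proteins = {e.peptide.peptide_id: ",".join(sorted(e.peptide.source_proteins))
                for e in design}
    rows = []
    for p in pairs:
        if p.significant and p.mean > 0.5:
            call = "enabling"
        elif p.significant and p.mean < 0.5:
            call = "disabling"
        else:
            call = "neutral"
        rows.append({
            "bait": p.bait, "prey": proteins.get(p.peptide_id, ""),
            "peptide_id": p.peptide_id, "site": p.site, "call": call,
            "mean_score": p.mean, "n": p.n, "p_value": p.p_value,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------- kinase enrichment

def kinase_enrichment(
    binders: set[str],
    background: set[str],
    kinase_map: Mapping[str, set[str]],
) -> pd.DataFrame:
    """Per-kinase enrichment of binders over the design background.

    One-sided Fisher exact tests (enrichment direction) on the 2x2 table
    (binder / non-binder background) x (has / lacks the kinase category),
    Holm-adjusted across kinases.  ``kinase_map`` maps an entry to the
    kinase categories predicted or known to phosphorylate it.
    """
    if not binders <= background:
        raise ScoringError("binder set must be a subset of the background")
    kinases = sorted({k for ks in kinase_map.values() for k in ks})
    n_bind, n_bg = len(binders), len(background)
    rows = []
    for kin in kinases:
        with_kin = {e for e in background if kin in kinase_map.get(e, ())}
        a = len(binders & with_kin)
        b = n_bind - a
        c = len(with_kin) - a
        d = (n_bg - n_bind) - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append({"kinase": kin, "binders_with": a, "binders_without": b,
                     "background_with": c, "background_without": d,
                     "p_value": float(p)})
    df = pd.DataFrame(rows)
    if len(df):
        _, adj, _, _ = multipletests(df.p_value, method="holm")
        df["p_adjusted"] = adj
    return df
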