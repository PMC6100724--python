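"""Human-readable summaries of scoring outputs.

Everything here is regenerable from the TSVs alone: per-bait wt/mimetic
pair bars, the position score heatmap with significance marks, and the
network edge table.  Rendering uses matplotlib's non-interactive backend.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402


def plot_position_heatmap(matrix: pd.DataFrame, path: str | Path) -> None:
    """Bait x p-index heatmap of pair scores; ``*`` marks q <= FDR cells."""
    baits = sorted(matrix.bait.unique())
    sites = sorted(matrix.site.unique())
    grid = np.full((len(baits), len(sites)), np.nan)
    for _, row in matrix.iterrows():
        grid[baits.index(row.bait), sites.index(row.site)] = row.mean_score
    fig, ax = plt.subplots(figsize=(1.2 * len(sites) + 2, 0.8 * len(baits) + 1.5))
    im = ax.imshow(grid, cmap="RdBu", vmin=0, vmax=1, aspect="auto")
    ax.set_xticks(range(len(sites)), [f"p{s}" for s in sites])
    ax.set_yticks(range(len(baits)), baits)
    for _, row in matrix.iterrows():
        i, j = baits.index(row.bait), sites.index(row.site)
        if row.get("call") == "untestable":
            ax.text(j, i, "n.t.", ha="center", va="center", fontsize=8)
        elif row.get("significant"):
            ax.text(j, i, "*", ha="center", va="center", fontsize=14)
    fig.colorbar(im, label="pair score (0 = wt-dominated, 1 = mimetic-dominated)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_pair_bars(pairs: pd.DataFrame, bait: str, path: str | Path) -> None:
    """Per-peptide wt (red) vs mimetic (blue) mean fractions for one bait."""
    sub = pairs[pairs.bait == bait].sort_values(["site", "peptide_id"])
    if sub.empty:
        return
    wt = [np.mean([float(x) for x in s.split(",")]) for s in sub.f_wt]
    mim = [np.mean([float(x) for x in s.split(",")]) for s in sub.f_mim]
    x = np.arange(len(sub))
    fig, ax = plt.subplots(figsize=(max(6, 0.45 * len(sub)), 4))
    ax.bar(x - 0.2, wt, width=0.4, color="firebrick", label="wild type")
    ax.bar(x + 0.2, mim, width=0.4, color="steelblue", label="phosphomimetic")
    labels = [f"{p} (p{s}){'*' if sig else ''}"
              for p, s, sig in zip(sub.peptide_id, sub.site, sub.significant)]
    ax.set_xticks(x, labels, rotation=90, fontsize=7)
    ax.set_ylabel("fraction of pool reads")
    ax.set_title(bait)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_pwm_ic(pwm_probs: pd.DataFrame, ic: pd.Series, path: str | Path) -> None:
    """Residue-probability heatmap with an information-content bar row."""
    fig, (ax0, ax1) = plt.subplots(2, 1, figsize=(8, 7), height_ratios=[1, 4],
                                   sharex=True)
    ax0.bar(range(len(ic)), ic.values, color="gray")
    ax0.set_ylabel("IC (bits)")
    im = ax1.imshow(pwm_probs.T.values, cmap="viridis", aspect="auto")
    ax1.set_yticks(range(len(pwm_probs.columns)), pwm_probs.columns, fontsize=7)
    ax1.set_xticks(range(len(pwm_probs.index)), [f"p{p}" for p in pwm_probs.index])
    fig.colorbar(im, ax=ax1, label="probability")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def render_report(score_dir: str | Path, out_dir: str | Path | None = None) -> Path:
    """Assemble a markdown report from a score run's TSV outputs."""
    score_dir = Path(score_dir)
    out_dir = score_dir if out_dir is None else Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lines = ["# Phosphomimetic selection report", ""]

    matrix_path = score_dir / "position_matrix.tsv"
    pairs_path = score_dir / "pair_scores.tsv"
    if matrix_path.is_file():
        matrix = pd.read_csv(matrix_path, sep="\t")
        if matrix.empty:
            lines += ["No testable position cells (empty high-confidence set).", ""]
        else:
            plot_position_heatmap(matrix, out_dir / "position_heatmap.png")
            lines += ["## Position score matrix", "",
                      "![position heatmap](position_heatmap.png)", "",
                      matrix.to_markdown(index=False), ""]
    if pairs_path.is_file():
        pairs = pd.read_csv(pairs_path, sep="\t")
        if pairs.empty:
            lines += ["No scorable wt/mimetic pairs.", ""]
        else:
            lines += ["## Pair scores per bait", ""]
            for bait in sorted(pairs.bait.unique()):
                png = f"pairs_{bait}.png"
                plot_pair_bars(pairs, bait, out_dir / png)
                lines += [f"### {bait}", "", f"![{bait}]({png})", ""]
    edges_path = score_dir / "network_edges.tsv"
    if edges_path.is_file():
        edges = pd.read_csv(edges_path, sep="\t")
        lines += ["## Network edges", "",
                  edges.to_markdown(index=False) if len(edges) else "No edges.", ""]
    out = out_dir / "report.md"
    out.write_text("\n".join(lines))
    return out
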