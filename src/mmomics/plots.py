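"""Figure exports: per-class lipid dot plot, concordance bars, ROC curve."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402

from .lipids import parse_lipid_name, LipidNameError  # noqa: E402

__all__ = ["plot_class_dotplot", "plot_concordance_bars", "plot_roc"]


def plot_class_dotplot(results: pd.DataFrame, enrich: pd.DataFrame, path) -> None:
    """Per-lipid logFC grouped by class; significantly enriched classes red.

    ``results`` is a differential table indexed by lipid name; ``enrich``
    an enrichment table indexed by set id (``class:<name>`` rows used).
    """
    classes: dict[str, list[float]] = {}
    for name, lfc in results["logFC"].dropna().items():
        try:
            cls = parse_lipid_name(str(name)).lipid_class
        except LipidNameError:
            continue
        classes.setdefault(cls, []).append(float(lfc))
    sig = {sid.split(":", 1)[1] for sid in enrich.index
           if sid.startswith("class:")
           and enrich.loc[sid, "adj_p_value"] < 0.05}
    order = sorted(classes)
    fig, ax = plt.subplots(figsize=(max(6, 0.5 * len(order)), 4))
    for i, cls in enumerate(order):
        color = "red" if cls in sig else "grey"
        ax.plot([i] * len(classes[cls]), classes[cls], "o", ms=4,
                color=color, alpha=0.7)
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xticks(range(len(order)), order, rotation=60, ha="right")
    ax.set_ylabel("logFC")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_concordance_bars(summaries: dict[str, dict], path) -> None:
    """Grouped bars: significant in A, also in B, same direction."""
    keys = list(summaries)
    fig, ax = plt.subplots(figsize=(2 + 2 * len(keys), 4))
    width = 0.25
    for i, key in enumerate(keys):
        s = summaries[key]
        ax.bar(i - width, s["n_sig_A"], width, color="tab:red",
               label="significant (A)" if i == 0 else None)
        ax.bar(i, s["n_overlap"], width, color="tab:green",
               label="also significant (B)" if i == 0 else None)
        ax.bar(i + width, s["n_same_direction"], width, color="tab:blue",
               label="same direction" if i == 0 else None)
    ax.set_xticks(range(len(keys)), keys)
    ax.set_ylabel("count")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_roc(roc: dict, path) -> None:
    """Overall and per-component ROC curves of the path classifier."""
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(roc["roc"]["fpr"], roc["roc"]["tpr"],
            label=f"complete (AUC={roc['auc']:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.5)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
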