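"""Multiple-testing thresholding and presentation surfaces.

Results for many exposure × outcome pairs are summarised two ways: a
heat-map style grid of p-values (starred below the Bonferroni-corrected
threshold, signed by effect direction) and a side-by-side comparison table
of the main IV estimate, the split-sample combination and the
multivariable-adjusted association, with the endogeneity p-value.

Exact numeric values always live in the tab-separated text outputs; the
matplotlib renderings are presentation only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .estimates import MREstimate, MetaResult, EndogeneityResult

__all__ = [
    "bonferroni_threshold", "build_heatmap_table", "forest_table",
    "ResultsGrid", "plot_heatmap", "plot_forest",
]


def bonferroni_threshold(alpha: float = 0.05, n_outcomes: int = 19) -> float:
    """Family-wise corrected p-value threshold: alpha / number of outcomes.

    Correction is across outcomes only (no correction for multiple
    exposures); the conventional alpha 0.05 over 19 outcomes gives 0.0026
    to two significant figures.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if n_outcomes < 1:
        raise ValueError("n_outcomes must be >= 1")
    return alpha / n_outcomes


@dataclass
class ResultsGrid:
    """Exposures × outcomes grid of p-values with star/sign annotations.

    Stored tidy (one row per cell); ``pivot()`` gives the wide rendering.
    A cell is starred iff its p-value is strictly below the threshold.
    A beta of exactly zero gets sign "0", is never starred, and is flagged
    for review.
    """

    cells: pd.DataFrame   # exposure, outcome, p, beta, sign, starred, flagged, method
    threshold: float

    def pivot(self, annotate: bool = True) -> pd.DataFrame:
        df = self.cells.copy()
        if annotate:
            df["cell"] = [
                f"{p:.2e}{'*' if s else ''}{sign}"
                for p, s, sign in zip(df["p"], df["starred"], df["sign"])
            ]
            values = "cell"
        else:
            values = "p"
        wide = df.pivot(index="exposure", columns="outcome", values=values)
        return wide

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# threshold\t{self.threshold!r}\n")
            self.cells.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ResultsGrid":
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("# threshold\t"):
                raise ValueError("not a results-grid file")
            threshold = float(header.split("\t", 1)[1])
            cells = pd.read_csv(fh, sep="\t")
        cells["sign"] = cells["sign"].astype(str)
        return cls(cells=cells, threshold=threshold)


def _iter_keyed(results) -> Iterable[Tuple[str, str, MREstimate]]:
    if isinstance(results, Mapping):
        for (exposure, outcome), est in results.items():
            yield exposure, outcome, est
    else:
        for exposure, outcome, est in results:
            yield exposure, outcome, est


def build_heatmap_table(results, threshold: float) -> ResultsGrid:
    """Assemble the p-value grid from estimates keyed by exposure × outcome.

    ``results`` is a mapping ``{(exposure, outcome): MREstimate}`` or an
    iterable of ``(exposure, outcome, estimate)``. Duplicate keys are an
    error; pairs never analysed are simply absent (rendered blank by
    ``pivot``).
    """
    rows = []
    seen = set()
    for exposure, outcome, est in _iter_keyed(results):
        key = (exposure, outcome)
        if key in seen:
            raise ValueError(f"duplicate exposure x outcome key: {key}")
        seen.add(key)
        if est.beta > 0:
            sign = "+"
        elif est.beta < 0:
            sign = "-"
        else:
            sign = "0"
        starred = bool(est.p < threshold) and sign != "0"
        rows.append({
            "exposure": exposure, "outcome": outcome,
            "p": est.p, "beta": est.beta, "sign": sign,
            "starred": starred, "flagged": sign == "0",
            "method": est.method,
        })
    cells = pd.DataFrame(
        rows, columns=["exposure", "outcome", "p", "beta", "sign",
                       "starred", "flagged", "method"],
    )
    return ResultsGrid(cells=cells, threshold=threshold)


def _interval(est, scale: float, fmt: str) -> str:
    if est is None:
        return ""
    return (f"{est.beta * scale:{fmt}} "
            f"({est.ci_low * scale:{fmt}} to {est.ci_high * scale:{fmt}})")


def forest_table(
    main: Optional[MREstimate],
    split: Optional[MetaResult],
    adjusted: Optional[MREstimate],
    endo: Optional[EndogeneityResult],
    exposure: str = "",
    outcome: str = "",
    unit_label: str = "",
    scale: float = 1.0,
    percent: bool = False,
) -> dict:
    """One comparison row: main IV, split-sample and adjusted estimates.

    ``scale`` rescales effects to the display convention (per 5 units/week,
    per 5 kg/m², per SD...); ``percent`` additionally multiplies by 100 to
    show risk differences as absolute percentage changes. Absent analyses
    produce blank cells, and the row is emitted regardless.
    """
    if main is None and split is None and adjusted is None:
        raise ValueError("at least one estimate must be present")
    disp = scale * (100.0 if percent else 1.0)
    fmt = ".1f" if percent else ".3g"
    label = f"{exposure} ({unit_label})" if unit_label else exposure
    return {
        "exposure": label,
        "outcome": outcome,
        "n": main.n if main is not None else (adjusted.n if adjusted else ""),
        "main_mr": _interval(main, disp, fmt),
        "main_mr_p": main.p if main is not None else "",
        "split_mr": _interval(split, disp, fmt),
        "split_mr_p": split.p if split is not None else "",
        "adjusted": _interval(adjusted, disp, fmt),
        "adjusted_p": adjusted.p if adjusted is not None else "",
        "endogeneity_p": endo.p if endo is not None else "",
    }


# ---------------------------------------------------------------------------
# optional matplotlib renderings (presentation only)

def plot_heatmap(grid: ResultsGrid, path) -> None:
    """Render the p-value grid; cell intensity increases as p decreases."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    wide = grid.pivot(annotate=False)
    logp = -np.log10(wide.to_numpy(float))
    fig, ax = plt.subplots(
        figsize=(1.0 + 0.6 * wide.shape[1], 1.0 + 0.5 * wide.shape[0])
    )
    im = ax.imshow(logp, cmap="Reds", aspect="auto")
    ax.set_xticks(range(wide.shape[1]), wide.columns, rotation=45, ha="right")
    ax.set_yticks(range(wide.shape[0]), wide.index)
    ann = grid.cells.set_index(["exposure", "outcome"])
    for i, ex in enumerate(wide.index):
        for j, out in enumerate(wide.columns):
            if (ex, out) in ann.index:
                row = ann.loc[(ex, out)]
                txt = f"{row['sign']}{'*' if row['starred'] else ''}"
                ax.text(j, i, txt, ha="center", va="center", fontsize=9)
    fig.colorbar(im, ax=ax, label="-log10 p")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_forest(rows: Iterable[dict], estimates: Iterable, path) -> None:
    """Simple forest plot of (label, MREstimate-like) pairs."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels, betas, los, his = [], [], [], []
    for label, est in estimates:
        labels.append(label)
        betas.append(est.beta)
        los.append(est.ci_low)
        his.append(est.ci_high)
    y = np.arange(len(labels))[::-1]
    fig, ax = plt.subplots(figsize=(6, 1 + 0.4 * len(labels)))
    ax.errorbar(betas, y,
                xerr=[np.array(betas) - np.array(los),
                      np.array(his) - np.array(betas)],
                fmt="s", color="black", capsize=3)
    ax.axvline(0.0, color="grey", lw=0.8, ls="--")
    ax.set_yticks(y, labels)
    ax.set_xlabel("effect (95% CI)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
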