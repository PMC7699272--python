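"""Relative qPCR quantification by the comparative-CT (delta-delta-CT) method.

Target-gene CT values are normalised per sample against the arithmetic mean
of two reference-gene CTs (B2M and RLP13a by default) — on the 2^-CT
expression scale this is the geometric mean of the reference levels — and
then against the mean delta-CT of the same-day control samples:

    dCT  = CT(gene) - mean(CT(ref1), CT(ref2))
    ddCT = dCT - mean(dCT of controls, same gene & day)
    relative expression = 2 ** (-ddCT)

Amplification efficiency is fixed at 2 (no efficiency correction).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_REFERENCE_GENES",
    "validate_ct_table",
    "delta_ct",
    "relative_expression",
    "summarize_expression",
    "make_ct_table",
]

DEFAULT_REFERENCE_GENES = ("B2M", "RLP13a")

_REQUIRED = ("sample", "group", "day", "gene", "ct")


def validate_ct_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _REQUIRED if c not in table.columns]
    if missing:
        raise ValueError(f"CT table missing columns: {missing}")
    if not np.isfinite(table["ct"]).all():
        raise ValueError("CT values must be finite")
    return table


def delta_ct(
    table: pd.DataFrame,
    reference_genes: tuple[str, str] = DEFAULT_REFERENCE_GENES,
) -> pd.DataFrame:
    """Per-sample delta-CT for every gene (reference genes included).

    Raises if any sample lacks one of the two reference genes, naming the
    sample.
    """
    validate_ct_table(table)
    refs = table[table["gene"].isin(reference_genes)]
    ref_mean = refs.groupby("sample")["ct"].agg(["mean", "size"])
    bad = ref_mean.index[ref_mean["size"] != len(set(reference_genes))]
    missing_all = set(table["sample"]) - set(ref_mean.index)
    if len(bad) or missing_all:
        culprit = sorted(set(bad) | missing_all)[0]
        raise ValueError(
            f"sample {culprit!r} does not carry both reference genes "
            f"{tuple(reference_genes)}"
        )
    out = table.copy()
    out["delta_ct"] = out["ct"] - out["sample"].map(ref_mean["mean"])
    return out


def relative_expression(
    table: pd.DataFrame,
    reference_genes: tuple[str, str] = DEFAULT_REFERENCE_GENES,
    control_group: str = "control",
) -> pd.DataFrame:
    """Per-sample relative expression 2^-ddCT, calibrated per (gene, day).

    The calibrator is the arithmetic mean delta-CT of the ``control_group``
    samples for the same gene at the same day, so the control-group mean
    delta-delta-CT is exactly 0 — but note the control *fold-change* mean
    (mean of 2^-ddCT) is 1 only up to Jensen's inequality; the conventional
    report normalises per-sample values so the control geometric mean is 1.
    """
    d = delta_ct(table, reference_genes)
    ctrl = (
        d[d["group"] == control_group]
        .groupby(["gene", "day"])["delta_ct"]
        .mean()
        .rename("calibrator")
    )
    d = d.join(ctrl, on=["gene", "day"])
    if d["calibrator"].isna().any():
        row = d[d["calibrator"].isna()].iloc[0]
        raise ValueError(
            f"no {control_group!r} sample for gene {row['gene']!r} at day {row['day']}"
        )
    d["delta_delta_ct"] = d["delta_ct"] - d["calibrator"]
    d["relative_expression"] = 2.0 ** (-d["delta_delta_ct"])
    return d


def summarize_expression(per_sample: pd.DataFrame) -> pd.DataFrame:
    """Mean, SEM and n of relative expression per (gene, group, day).

    SEM is computed on the fold-change (2^-ddCT) scale; the log2-scale
    mean and SEM of ddCT are emitted alongside for reference.
    """
    def _sem(x: pd.Series) -> float:
        return float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0

    g = per_sample.groupby(["gene", "group", "day"])
    out = g.agg(
        n=("relative_expression", "size"),
        mean_expression=("relative_expression", "mean"),
        sem_expression=("relative_expression", _sem),
        mean_ddct=("delta_delta_ct", "mean"),
        sem_ddct=("delta_delta_ct", _sem),
    ).reset_index()
    return out


# --------------------------------------------------------------------------
# synthetic CT tables

#: fold-change trajectories (bleomycin vs control) for a few fibrosis genes;
#: collagen and LOX induction build toward the fibrotic phase.
_DEFAULT_EFFECTS = {
    "Col1a1": {0: 1.0, 7: 2.0, 14: 4.0, 21: 6.0, 28: 8.0},
    "Col3a1": {0: 1.0, 7: 2.0, 14: 3.0, 21: 4.0, 28: 5.0},
    "Lox": {0: 1.0, 7: 3.0, 14: 4.0, 21: 3.5, 28: 3.0},
    "Il1b": {0: 1.0, 7: 6.0, 14: 3.0, 21: 2.0, 28: 1.5},
}


def make_ct_table(
    days: tuple[int, ...] = (0, 7, 14, 21, 28),
    n_per_group: int = 5,
    effects: dict[str, dict[int, float]] | None = None,
    reference_genes: tuple[str, str] = DEFAULT_REFERENCE_GENES,
    ct_noise_sd: float = 0.15,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a long-format qPCR CT table with known fold changes.

    Each sample receives reference CTs near 20/22 plus a sample-specific
    loading offset (which delta-CT must cancel), and target CTs shifted by
    -log2(fold change) for bleomycin samples.  Technical noise is Gaussian
    on the CT scale.
    """
    effects = effects or _DEFAULT_EFFECTS
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 53]))
    base_ct = {gene: rng.uniform(22.0, 28.0) for gene in effects}
    ref_base = dict(zip(reference_genes, (20.0, 22.0)))
    rows = []
    for day in days:
        for group in ("control", "bleomycin"):
            for i in range(n_per_group):
                sample = f"{group[:4]}_{day}_{i}"
                loading = rng.normal(0.0, 0.5)  # common shift, cancels in dCT
                for ref, b in ref_base.items():
                    rows.append(
                        dict(sample=sample, group=group, day=day, gene=ref,
                             ct=b + loading + rng.normal(0, ct_noise_sd),
                             is_reference=True)
                    )
                for gene, curve in effects.items():
                    fold = curve.get(day, 1.0) if group == "bleomycin" else 1.0
                    ct = base_ct[gene] - np.log2(fold) + loading
                    rows.append(
                        dict(sample=sample, group=group, day=day, gene=gene,
                             ct=ct + rng.normal(0, ct_noise_sd),
                             is_reference=False)
                    )
    return pd.DataFrame(rows)
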