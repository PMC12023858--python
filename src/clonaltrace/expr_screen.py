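"""Candidate-gene screening: DEG thresholds, intersection, trait filters.

The screening funnel used to nominate nitrogen-transport candidates from
an organ × stage expression panel:

1. per-organ differential expression between two stages (thresholds
   p < 0.05 and |log₂FC| ≥ 1, applied to supplied DE tables, or to a
   built-in two-sample stand-in when none are given — the stand-in is a
   Welch t-test on log₂(FPKM+1) and is *not* DESeq2);
2. intersection of the per-organ DEG sets (the Venn core);
3. a trait-correlation filter keeping genes whose expression correlates
   with all four physiological traits (TN, NH₄⁺, NO₃⁻, soluble protein);
4. an FPKM abundance floor and a ¹⁵N-content correlation screen;
5. RT-qPCR quantification by the 2^−ΔΔCt method.

Gene sets narrow monotonically through the funnel: the common set is a
subset of every per-organ set, the trait-correlated set a subset of the
common set.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TRAITS",
    "ScreenResult",
    "call_degs",
    "intersect_organs",
    "trait_screen",
    "fpkm_floor_filter",
    "isotope_correlation",
    "delta_delta_ct",
    "run_screen",
    "bh_adjust",
]

TRAITS = ("TN", "NH4", "NO3", "soluble_protein")


@dataclass
class ScreenResult:
    """Surviving gene sets at each funnel step plus the correlation edges."""

    degs_per_organ: dict[str, set] = field(default_factory=dict)
    common_degs: set = field(default_factory=set)
    trait_correlated: set = field(default_factory=set)
    edges: pd.DataFrame | None = None
    venn_counts: dict[frozenset, int] = field(default_factory=dict)

    def check_nesting(self) -> None:
        """Raise if the funnel's subset chain is violated."""
        for organ, degs in self.degs_per_organ.items():
            if not self.common_degs <= degs:
                raise AssertionError(
                    f"common DEGs are not a subset of the {organ} DEG set"
                )
        if not self.trait_correlated <= self.common_degs:
            raise AssertionError(
                "trait-correlated genes are not a subset of the common DEGs"
            )


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (reported alongside raw p)."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(ranked, 1.0)
    return out


def call_degs(
    fpkm: pd.DataFrame,
    groups: pd.Series | dict | None = None,
    *,
    de_table: pd.DataFrame | None = None,
    p_thresh: float = 0.05,
    lfc_thresh: float = 1.0,
) -> pd.DataFrame:
    """Differentially expressed genes at p < ``p_thresh`` and |log₂FC| ≥ ``lfc_thresh``.

    When ``de_table`` (columns ``gene, log2fc, p``) is supplied — e.g. a
    DESeq2 export — only the thresholds are applied. Otherwise a
    built-in stand-in computes a Welch t-test on log₂(FPKM+1) between
    the two sample groups given by ``groups`` (sample → group label);
    the stand-in is a screening convenience, not DESeq2.

    Returns a table of passing genes with ``log2fc, p, p_adj``.
    """
    if de_table is not None:
        tbl = de_table.copy()
        required = {"gene", "log2fc", "p"}
        if not required <= set(tbl.columns):
            raise ValueError(f"de_table needs columns {sorted(required)}")
    else:
        if groups is None:
            raise ValueError("either de_table or groups must be supplied")
        groups = pd.Series(dict(groups)) if not isinstance(groups, pd.Series) else groups
        labels = [lbl for lbl in pd.unique(groups) if pd.notna(lbl)]
        if len(labels) != 2:
            raise ValueError(f"need exactly two groups, got {labels}")
        cols_a = groups.index[groups == labels[0]]
        cols_b = groups.index[groups == labels[1]]
        if len(cols_a) < 2 or len(cols_b) < 2:
            raise ValueError("each group needs at least two replicates")
        log_a = np.log2(fpkm[cols_a].to_numpy(dtype=float) + 1.0)
        log_b = np.log2(fpkm[cols_b].to_numpy(dtype=float) + 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t, p = sps.ttest_ind(log_b, log_a, axis=1, equal_var=False)
        p = np.where(np.isnan(p), 1.0, p)
        tbl = pd.DataFrame(
            {
                "gene": fpkm.index,
                "log2fc": log_b.mean(axis=1) - log_a.mean(axis=1),
                "p": p,
            }
        )
    tbl["p_adj"] = bh_adjust(tbl["p"].to_numpy())
    passing = tbl[(tbl["p"] < p_thresh) & (tbl["log2fc"].abs() >= lfc_thresh)]
    return passing.reset_index(drop=True)


def intersect_organs(degs_per_organ: dict[str, set]) -> tuple[set, dict]:
    """Strict intersection of per-organ DEG sets, plus all Venn region counts.

    Venn regions are keyed by the frozenset of organs a gene is exclusive
    to; only non-empty memberships are counted.
    """
    if len(degs_per_organ) < 2:
        raise ValueError("need at least two organ DEG sets to intersect")
    organs = list(degs_per_organ)
    common = set.intersection(*(set(s) for s in degs_per_organ.values()))
    venn: dict[frozenset, int] = {}
    for r in range(1, len(organs) + 1):
        for combo in itertools.combinations(organs, r):
            inside = set.intersection(*(set(degs_per_organ[o]) for o in combo))
            outside = set.union(
                set(), *(set(degs_per_organ[o]) for o in organs if o not in combo)
            )
            venn[frozenset(combo)] = len(inside - outside)
    return common, venn


def _cell_means(
    fpkm: pd.DataFrame, samples: pd.DataFrame
) -> tuple[np.ndarray, list[tuple[str, str]]]:
    """Mean FPKM per (organ, stage) cell; columns follow the cell list."""
    cells = (
        samples[["organ", "stage"]].drop_duplicates().itertuples(index=False)
    )
    cells = [(c.organ, c.stage) for c in cells]
    mat = np.empty((fpkm.shape[0], len(cells)))
    for j, (organ, stage) in enumerate(cells):
        cols = samples.loc[
            (samples["organ"] == organ) & (samples["stage"] == stage), "sample"
        ]
        mat[:, j] = fpkm[cols].mean(axis=1)
    return mat, cells


def _pearson_rows(mat: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Pearson r and two-sided t-test p of ``mat`` against ``y``."""
    n = y.size
    xm = mat - mat.mean(axis=1, keepdims=True)
    ym = y - y.mean()
    sx = np.sqrt((xm**2).sum(axis=1))
    sy = np.sqrt((ym**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xm @ ym) / (sx * sy)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * sps.t.sf(np.abs(t), n - 2)
    p = np.where(np.isfinite(t), p, 0.0)
    r = np.where(sx > 0, r, np.nan)
    return r, np.where(np.isnan(r), np.nan, p)


def trait_screen(
    fpkm: pd.DataFrame,
    samples: pd.DataFrame,
    traits: pd.DataFrame,
    *,
    p_thresh: float = 0.05,
    require_all: int = 4,
) -> tuple[set, pd.DataFrame]:
    """Keep genes whose expression correlates with the physiological traits.

    Expression and traits are paired on (organ, stage) means. A gene
    survives when its Pearson p-value is below ``p_thresh`` for at least
    ``require_all`` of the four traits (all four by default). Returns
    the surviving gene set and the full edge list
    (gene, trait, r, p, p_adj) for network export; genes with constant
    expression are excluded with a warning.
    """
    mat, cells = _cell_means(fpkm, samples)
    trait_tbl = traits.set_index(["organ", "stage"]).loc[cells]
    constant = np.ptp(mat, axis=1) == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} gene(s) constant across cells excluded "
            "from the trait screen",
            UserWarning,
            stacklevel=2,
        )
    edges = []
    pass_counts = np.zeros(fpkm.shape[0], dtype=int)
    for trait in TRAITS:
        y = trait_tbl[trait].to_numpy(dtype=float)
        r, p = _pearson_rows(mat, y)
        p_adj = bh_adjust(np.where(np.isnan(p), 1.0, p))
        pass_counts += (~constant) & (p < p_thresh)
        edges.append(
            pd.DataFrame(
                {"gene": fpkm.index, "trait": trait, "r": r, "p": p, "p_adj": p_adj}
            )
        )
    kept = set(fpkm.index[(pass_counts >= require_all) & ~constant])
    edge_df = pd.concat(edges, ignore_index=True)
    edge_df = edge_df[edge_df["gene"].isin(fpkm.index[~constant])]
    return kept, edge_df.reset_index(drop=True)


def fpkm_floor_filter(
    fpkm: pd.DataFrame,
    samples: pd.DataFrame | None = None,
    *,
    organ: str | None = None,
    floor: float = 10.0,
) -> set:
    """Genes whose mean FPKM (optionally within one organ) is ≥ ``floor``.

    The boundary is inclusive: a gene averaging exactly the floor passes.
    """
    if organ is not None:
        if samples is None:
            raise ValueError("samples metadata required to filter by organ")
        cols = samples.loc[samples["organ"] == organ, "sample"]
        means = fpkm[cols].mean(axis=1)
    else:
        means = fpkm.mean(axis=1)
    return set(fpkm.index[means >= floor])


def isotope_correlation(
    fpkm: pd.DataFrame,
    samples: pd.DataFrame,
    n15_content: pd.DataFrame,
    *,
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Per-(gene, organ) Pearson correlation against the ¹⁵N trajectory.

    ``n15_content`` is a tidy table (organ, stage, n15_content_g);
    expression is paired on stage means within each organ. Cells with
    fewer than ``min_pairs`` stages or constant expression are returned
    blank (NaN r, empty stars). Stars mark p < 0.05 (*) and p < 0.01 (**).
    """
    rows = []
    for organ, traj in n15_content.groupby("organ", observed=True):
        traj = traj.set_index("stage")["n15_content_g"]
        stages = [s for s in traj.index]
        cols_by_stage = {
            s: samples.loc[
                (samples["organ"] == organ) & (samples["stage"] == s), "sample"
            ]
            for s in stages
        }
        stages = [s for s in stages if len(cols_by_stage[s])]
        if len(stages) < min_pairs:
            continue
        expr = np.column_stack(
            [fpkm[cols_by_stage[s]].mean(axis=1) for s in stages]
        )
        y = traj.loc[stages].to_numpy(dtype=float)
        r, p = _pearson_rows(expr, y)
        for gene, ri, pi in zip(fpkm.index, r, p):
            stars = "" if np.isnan(pi) else "**" if pi < 0.01 else "*" if pi < 0.05 else ""
            rows.append(
                {"gene": gene, "organ": organ, "r": ri, "p": pi, "stars": stars}
            )
    return pd.DataFrame(rows)


def delta_delta_ct(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_cal: float,
    ct_ref_cal: float,
) -> float:
    """Relative expression by the 2^−ΔΔCt method.

    ΔΔCt = (Ct_target − Ct_reference)_sample − (Ct_target − Ct_reference)_calibrator.
    """
    cts = (ct_target_sample, ct_ref_sample, ct_target_cal, ct_ref_cal)
    if not all(np.isfinite(cts)):
        raise ValueError("all Ct values must be finite")
    ddct = (ct_target_sample - ct_ref_sample) - (ct_target_cal - ct_ref_cal)
    return float(2.0 ** (-ddct))


def run_screen(
    fpkm: pd.DataFrame,
    samples: pd.DataFrame,
    traits: pd.DataFrame,
    *,
    stage_pair: tuple[str, str] = ("ES", "PS"),
    de_tables: dict[str, pd.DataFrame] | None = None,
    p_thresh: float = 0.05,
    lfc_thresh: float = 1.0,
    require_all: int = 4,
) -> ScreenResult:
    """The full screening funnel: per-organ DEGs → intersection → trait filter.

    DEGs are called per organ between ``stage_pair`` (supplied DE tables
    take precedence over the built-in stand-in), intersected across
    organs, and the common set is filtered for correlation with all four
    physiological traits. Nesting of the surviving sets is checked
    before returning.
    """
    organs = list(pd.unique(samples["organ"]))
    degs_per_organ: dict[str, set] = {}
    for organ in organs:
        if de_tables is not None and organ in de_tables:
            passing = call_degs(
                fpkm, de_table=de_tables[organ],
                p_thresh=p_thresh, lfc_thresh=lfc_thresh,
            )
        else:
            sub = samples[
                (samples["organ"] == organ) & (samples["stage"].isin(stage_pair))
            ]
            groups = pd.Series(
                sub["stage"].to_numpy(), index=sub["sample"].to_numpy()
            )
            passing = call_degs(
                fpkm, groups, p_thresh=p_thresh, lfc_thresh=lfc_thresh
            )
        degs_per_organ[organ] = set(passing["gene"])
    common, venn = intersect_organs(degs_per_organ)
    if common:
        kept, edges = trait_screen(
            fpkm.loc[sorted(common)],
            samples,
            traits,
            p_thresh=p_thresh,
            require_all=require_all,
        )
    else:
        kept, edges = set(), pd.DataFrame(
            columns=["gene", "trait", "r", "p", "p_adj"]
        )
    result = ScreenResult(
        degs_per_organ=degs_per_organ,
        common_degs=common,
        trait_correlated=kept,
        edges=edges,
        venn_counts=venn,
    )
    result.check_nesting()
    return result
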