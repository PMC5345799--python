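"""Assignment of point and interval features to D/E domains.

Genes are represented by their TSS position; a feature belongs to the
unique half-open domain interval containing it. Features falling in
unassigned gaps are reported separately and excluded from the D/E fraction
denominator, so D + E fractions sum to 1 over assigned features.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genome import DomainMap, FeatureSet, Interval

__all__ = [
    "assign_points",
    "state_composition",
    "expression_breadth_fractions",
    "EXPRESSION_THRESHOLD",
]

EXPRESSION_THRESHOLD = 300.0  # tiling-array score separating expressed genes


def _assign_labels(features: FeatureSet, dmap: DomainMap) -> pd.Series:
    """Domain label per feature ('D', 'E' or None for gaps/uncovered)."""
    labels = np.full(len(features), None, dtype=object)
    df = features.df
    for chrom in df["chrom"].unique():
        ivs = dmap.on(str(chrom))
        if not ivs:
            continue
        starts = np.array([iv.start for iv in ivs])
        ends = np.array([iv.end for iv in ivs])
        lab = np.array([iv.label for iv in ivs], dtype=object)
        mask = (df["chrom"] == chrom).to_numpy()
        pos = df.loc[mask, "pos"].to_numpy()
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = (idx >= 0) & (pos < ends[np.clip(idx, 0, len(ivs) - 1)])
        vals = np.full(len(pos), None, dtype=object)
        vals[ok] = lab[idx[ok]]
        labels[mask] = vals
    return pd.Series(labels, index=df.index)


def assign_points(features: FeatureSet, dmap: DomainMap) -> pd.DataFrame:
    """Per-class counts and fractions of features in D, E and gaps.

    Fractions are over assigned (D or E) features; gap counts are reported
    but excluded from the denominator. Raises if a feature lies beyond its
    chromosome's covered extent and outside every interval's chromosome.
    """
    for chrom in features.df["chrom"].unique():
        if str(chrom) not in dmap.chromosomes():
            row = features.df[features.df["chrom"] == chrom].iloc[0]
            raise ValueError(
                f"feature at {row['chrom']}:{row['pos']} on chromosome "
                "absent from domain map"
            )
    domain = _assign_labels(features, dmap)
    df = features.df.assign(domain=domain)
    df["label"] = df["label"].fillna("all")
    rows = []
    for cls, sub in df.groupby("label"):
        n_d = int((sub["domain"] == "D").sum())
        n_e = int((sub["domain"] == "E").sum())
        n_gap = int(sub["domain"].isna().sum())
        assigned = n_d + n_e
        rows.append(
            {
                "class": cls,
                "n_d": n_d,
                "n_e": n_e,
                "n_gap": n_gap,
                "frac_d": n_d / assigned if assigned else np.nan,
                "frac_e": n_e / assigned if assigned else np.nan,
            }
        )
    return pd.DataFrame(rows)


def state_composition(dmap: DomainMap, annotation: list[Interval]) -> pd.DataFrame:
    """Base-pair composition of D and E domains by annotation label.

    For each domain label, the bp overlap with each annotation label
    (e.g. the five chromatin-state colours) normalized to the total
    overlapped bp of that domain label. Annotation intervals must not
    overlap each other.
    """
    ann = sorted(annotation, key=lambda iv: (iv.chrom, iv.start))
    for a, b in zip(ann, ann[1:]):
        if a.chrom == b.chrom and b.start < a.end:
            raise ValueError(f"overlapping annotation intervals {a} / {b}")
    overlaps: dict[tuple[str, str], int] = {}
    for dom in dmap:
        if dom.label is None:
            continue
        for iv in ann:
            if iv.chrom != dom.chrom:
                continue
            bp = min(dom.end, iv.end) - max(dom.start, iv.start)
            if bp > 0:
                key = (dom.label, iv.label or ".")
                overlaps[key] = overlaps.get(key, 0) + bp
    rows = []
    for dom_label in ("D", "E"):
        total = sum(v for (dl, _), v in overlaps.items() if dl == dom_label)
        for (dl, al), bp in sorted(overlaps.items()):
            if dl != dom_label:
                continue
            rows.append(
                {
                    "domain": dom_label,
                    "annotation": al,
                    "bp": bp,
                    "fraction": bp / total if total else np.nan,
                }
            )
    return pd.DataFrame(rows)


def expression_breadth_fractions(
    scores: pd.DataFrame,
    tss: FeatureSet,
    dmap: DomainMap,
    threshold: float = EXPRESSION_THRESHOLD,
    n_conditions: int | None = None,
) -> pd.DataFrame:
    """Expression-breadth classes split by domain.

    ``scores`` is indexed by gene with one column per condition (cell
    line). Breadth = number of conditions with score strictly greater
    than ``threshold``. Genes are assigned to D/E by the TSS whose
    ``label`` matches the gene name; genes missing from the TSS set are
    skipped and counted. Returns, per breadth value 0..n, the fraction of
    that breadth class falling in D and in E.
    """
    if n_conditions is None:
        n_conditions = scores.shape[1]
    if scores.shape[1] != n_conditions:
        raise ValueError("score table does not cover n_conditions columns")
    breadth = (scores.to_numpy(dtype=float) > threshold).sum(axis=1)
    gene_breadth = pd.Series(breadth, index=scores.index)
    domain = _assign_labels(tss, dmap)
    tss_domain = pd.Series(
        domain.to_numpy(), index=tss.df["label"].to_numpy()
    )
    tss_domain = tss_domain[~tss_domain.index.duplicated(keep="first")]
    rows = []
    n_missing = 0
    per_breadth: dict[int, dict[str, int]] = {
        b: {"D": 0, "E": 0} for b in range(n_conditions + 1)
    }
    for gene, b in gene_breadth.items():
        dom = tss_domain.get(gene)
        if dom is None or dom not in ("D", "E"):
            n_missing += 1
            continue
        per_breadth[int(b)][dom] += 1
    for b in range(n_conditions + 1):
        n_d, n_e = per_breadth[b]["D"], per_breadth[b]["E"]
        tot = n_d + n_e
        rows.append(
            {
                "breadth": b,
                "n_d": n_d,
                "n_e": n_e,
                "frac_d": n_d / tot if tot else np.nan,
                "frac_e": n_e / tot if tot else np.nan,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["n_skipped"] = n_missing
    return out
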