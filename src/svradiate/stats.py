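"""Statistical tests for the figure-level comparisons, and the report bundle.

Two chi-squared variants are provided — goodness-of-fit of observed SV
counts against genome-background proportions, and homogeneity of r×c
contingency tables across samples — plus the Mann-Whitney-Wilcoxon rank
test for INDEL size comparisons.  Statistics are computed here from
first principles (Pearson formula; midrank U with tie-corrected normal
approximation and continuity correction); only the chi-squared and
normal distribution functions come from scipy.

No multiple-testing correction is applied by default (per-panel exact P
values); Benjamini-Hochberg is available via :func:`bh_adjust`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm as norm_dist


@dataclass(frozen=True)
class GofResult:
    statistic: float
    df: int
    p_value: float
    observed: tuple
    expected: tuple
    low_expected_warning: bool

    def __post_init__(self) -> None:
        if self.statistic < 0 or not (0 <= self.p_value <= 1):
            raise ValueError("invalid chi-squared result")


@dataclass(frozen=True)
class RankTestResult:
    u_statistic: float
    p_value: float
    n1: int
    n2: int
    tie_warning: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.u_statistic <= self.n1 * self.n2):
            raise ValueError("U outside [0, n1*n2]")


def chisq_gof(
    observed: Sequence[float], expected_proportions: Sequence[float]
) -> GofResult:
    """Pearson goodness-of-fit test against stated proportions.

    ``statistic = Σ (O−E)²/E`` with ``E = N·p``; df = k−1; upper-tail p.
    """
    obs = np.asarray(observed, dtype=float)
    props = np.asarray(expected_proportions, dtype=float)
    if obs.shape != props.shape:
        raise ValueError("observed and proportions must have the same length")
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError("expected proportions must sum to 1")
    n = obs.sum()
    if n <= 0:
        raise ValueError("observed counts must sum to > 0")
    expected = n * props
    if np.any(expected == 0):
        raise ValueError(
            "zero expected count — pool that category with a neighbour first"
        )
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = obs.size - 1
    p = float(chi2_dist.sf(stat, df))
    return GofResult(
        statistic=stat, df=df, p_value=p,
        observed=tuple(float(o) for o in obs),
        expected=tuple(float(e) for e in expected),
        low_expected_warning=bool((expected < 5).any()),
    )


def chisq_homogeneity(table: Sequence[Sequence[float]]) -> GofResult:
    """Pearson chi-squared test on an r×c contingency table.

    ``E_ij = row_i · col_j / N``; df = (r−1)(c−1).
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or min(t.shape) < 2:
        raise ValueError("contingency table must have at least 2 rows and 2 columns")
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    if np.any(rows <= 0) or np.any(cols <= 0):
        raise ValueError("all row and column sums must be > 0")
    n = t.sum()
    expected = np.outer(rows, cols) / n
    stat = float(((t - expected) ** 2 / expected).sum())
    df = (t.shape[0] - 1) * (t.shape[1] - 1)
    p = float(chi2_dist.sf(stat, df))
    return GofResult(
        statistic=stat, df=df, p_value=p,
        observed=tuple(map(tuple, t)),
        expected=tuple(map(tuple, expected)),
        low_expected_warning=bool((expected < 5).any()),
    )


def _midranks(values: np.ndarray) -> np.ndarray:
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(values.size, dtype=float)
    i = 0
    while i < values.size:
        j = i
        while j + 1 < values.size and values[order[j + 1]] == values[order[i]]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> RankTestResult:
    """Two-sided Mann-Whitney-Wilcoxon test via the normal approximation.

    U is the statistic of the first sample (small U ⇒ first sample tends
    smaller); midranks handle ties, the variance carries the tie
    correction, and a 0.5 continuity correction is applied.  When every
    value is identical across both samples, p = 1 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    ranks = _midranks(combined)
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0

    _, tie_counts = np.unique(combined, return_counts=True)
    n = n1 + n2
    if np.all(tie_counts == n):  # all values identical
        return RankTestResult(u_statistic=float(u), p_value=1.0,
                              n1=n1, n2=n2, tie_warning=True)
    tie_term = ((tie_counts ** 3 - tie_counts).sum()) / (n * (n - 1))
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    mean_u = n1 * n2 / 2.0
    if var_u <= 0:
        return RankTestResult(u_statistic=float(u), p_value=1.0,
                              n1=n1, n2=n2, tie_warning=True)
    z = (u - mean_u - np.sign(u - mean_u) * 0.5) / np.sqrt(var_u)
    p = float(min(1.0, 2.0 * norm_dist.sf(abs(z))))
    return RankTestResult(u_statistic=float(u), p_value=p, n1=n1, n2=n2,
                          tie_warning=bool((tie_counts > 1).any()))


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg adjusted p-values (optional; off by default)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    prev = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        val = min(prev, p[i] * m / (rank_idx + 1))
        adj[i] = val
        prev = val
    return [float(v) for v in adj]


# ---------------------------------------------------------------------------
# report assembly

def _gof_to_dict(r: GofResult) -> dict:
    return {
        "statistic": r.statistic, "df": r.df, "p_value": r.p_value,
        "low_expected_warning": r.low_expected_warning,
    }


def build_report(
    sample_tables: dict,
    venn: dict | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Assemble the per-sample tables into one canonical report bundle.

    ``sample_tables`` maps sample_id to the dict of stage outputs for that
    sample (keys among ``sv_type_counts``, ``size_table``,
    ``element_distribution``, ``repair_summary``, ``origin_summary``);
    a 3-replicate ``venn`` partition may be attached.  Chi-squared tests
    of each sample's element and chromatin-state distributions against
    the genome background are added, each annotated with its inputs.

    The returned dict serialises to byte-identical JSON across reruns
    (keys sorted, floats emitted by ``repr``); when ``out_dir`` is given,
    ``report.json`` plus per-table TSVs are written there.
    """
    report: dict = {"samples": {}, "tests": {}}
    for sample_id in sorted(sample_tables):
        tables = sample_tables[sample_id]
        entry: dict = {}
        if "sv_type_counts" in tables:
            entry["sv_type_counts"] = dict(sorted(tables["sv_type_counts"].items()))
        if "size_table" in tables:
            entry["size_table"] = {
                k: {kk: vv for kk, vv in v.items() if kk != "lengths"}
                for k, v in tables["size_table"].items()
            }
        dist = tables.get("element_distribution")
        if dist is not None:
            entry["element_counts"] = dist["element_counts"]
            entry["type_element_counts"] = dist["type_element_counts"]
            entry["te_superfamily_counts"] = dist["te_superfamily_counts"]
            entry["chromatin_state_counts"] = dist["chromatin_state_counts"]
            entry["centromeric_fraction"] = dist["centromeric_fraction"]
            entry["hot_count"] = dist["hot_count"]
            entry["hot_fraction"] = dist["hot_fraction"]
            bg = dist["background_bp_fractions"]
            obs = [dist["element_counts"][c] for c in ("PCG", "TE", "IR")]
            if sum(obs) > 0 and min(bg.values()) > 0:
                gof = chisq_gof(obs, [bg[c] for c in ("PCG", "TE", "IR")])
                report["tests"][f"{sample_id}__element_vs_background"] = {
                    **_gof_to_dict(gof),
                    "test": "chisq_gof",
                    "observed": obs,
                    "expected_proportions": [bg[c] for c in ("PCG", "TE", "IR")],
                }
        rep = tables.get("repair_summary")
        if rep is not None:
            entry["repair_counts"] = rep["counts"]
            entry["repair_fractions"] = rep["fractions"]
            entry["mmej_mh_histogram"] = {
                str(k): v for k, v in rep["mmej_mh_histogram"].items()
            }
        orig = tables.get("origin_summary")
        if orig is not None:
            entry["origin_status_counts"] = orig["status_counts"]
            entry["donor_recipient_matrix"] = orig["donor_recipient_matrix"]
            entry["intrachromosomal_fraction"] = orig["intrachromosomal_fraction"]
        report["samples"][sample_id] = entry

    if venn is not None:
        report["venn"] = venn

    # cross-sample homogeneity of SV-type distributions where possible
    type_rows = {
        sid: t["sv_type_counts"]
        for sid, t in sorted(sample_tables.items())
        if t.get("sv_type_counts")
    }
    if len(type_rows) >= 2:
        all_types = sorted({k for row in type_rows.values() for k in row})
        table = [[row.get(t, 0) for t in all_types] for row in type_rows.values()]
        cols_ok = all(sum(col) > 0 for col in zip(*table))
        rows_ok = all(sum(r) > 0 for r in table)
        if len(all_types) >= 2 and cols_ok and rows_ok:
            hom = chisq_homogeneity(table)
            report["tests"]["sv_type_homogeneity"] = {
                **_gof_to_dict(hom),
                "test": "chisq_homogeneity",
                "samples": list(type_rows),
                "categories": all_types,
                "table": table,
            }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_report_json(report, out_dir / "report.json")
    return report


def write_report_json(report: dict, path: str | Path) -> None:
    """Canonical JSON serialisation: sorted keys, stable float formatting."""
    with open(path, "w") as fh:
        json.dump(report, fh, sort_keys=True, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
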