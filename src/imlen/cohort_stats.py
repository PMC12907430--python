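"""Cohort agreement statistics for intramural-length estimates.

Ships the 58-patient surgical AAOCA cohort table (per-patient
radiologic, computational and surgical IM lengths) as a packaged CSV
fixture and reproduces the agreement statistics: RMSE against the
surgical reference, mean error with sample SD, and the Wilcoxon
signed-rank comparison of the computational and radiologic methods.

Cell parsing follows the clinical-report conventions: a range "A-B"
(hyphen or en-dash) is replaced by its midpoint, and any value reported
as "short" is treated as 0 mm.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sps

from imlen.errors import CohortIntegrityWarning, CohortParseError

__all__ = [
    "parse_iml",
    "CohortTable",
    "load_cohort",
    "rmse",
    "error_summary",
    "wilcoxon_signed_rank",
    "cohort_report",
    "report_text",
]

EXPECTED_COUNTS = {"total": 58, "R-AAOCA": 49, "L-AAOCA": 9}

_RANGE_RE = re.compile(r"^\s*(\d+(?:\.\d+)?)\s*[–-]\s*(\d+(?:\.\d+)?)\s*$")
_NUMBER_RE = re.compile(r"^\s*\d+(?:\.\d+)?\s*$")


def parse_iml(raw: str | float) -> float:
    """Parse one IM-length cell to millimetres.

    Plain numbers map to themselves, ranges to their midpoint, and any
    string containing "short" (case-insensitive) to 0 mm. Idempotent on
    already-numeric input.
    """
    if isinstance(raw, (int, float)) and not isinstance(raw, bool):
        if np.isfinite(raw) and raw >= 0:
            return float(raw)
        raise CohortParseError(f"invalid numeric IM length: {raw!r}")
    s = str(raw).strip()
    if not s:
        raise CohortParseError("empty IM length cell")
    if "short" in s.lower():
        return 0.0
    m = _RANGE_RE.match(s)
    if m:
        return (float(m.group(1)) + float(m.group(2))) / 2.0
    if _NUMBER_RE.match(s):
        return float(s)
    raise CohortParseError(f"cannot parse IM length cell: {raw!r}")


def _anomaly_class(raw: str) -> str:
    s = str(raw).strip()
    if s.upper().startswith("L"):
        return "L-AAOCA"
    if s.upper().startswith("R"):
        return "R-AAOCA"
    raise CohortParseError(f"unknown anomaly class: {raw!r}")


@dataclass
class CohortTable:
    """Parsed cohort with the verbatim strings retained for provenance.

    ``records`` carries one row per patient with the raw cells
    (``radiologic``, ``computational``, ``surgical``), their parsed
    millimetre values (``*_mm``) and the anomaly class.
    """

    records: pd.DataFrame

    @classmethod
    def from_csv(cls, path) -> "CohortTable":
        df = pd.read_csv(path, dtype=str)
        required = {"patient", "anomaly", "radiologic", "computational", "surgical"}
        missing = required - set(df.columns)
        if missing:
            raise CohortParseError(f"cohort CSV missing columns: {sorted(missing)}")
        try:
            for col in ("radiologic", "computational", "surgical"):
                df[col + "_mm"] = df[col].map(parse_iml)
        except CohortParseError:
            raise
        except Exception as exc:
            raise CohortParseError(str(exc)) from exc
        df["anomaly_class"] = df["anomaly"].map(_anomaly_class)
        table = cls(records=df)
        counts = table.counts
        if (
            counts["total"] != EXPECTED_COUNTS["total"]
            or counts.get("R-AAOCA", 0) != EXPECTED_COUNTS["R-AAOCA"]
            or counts.get("L-AAOCA", 0) != EXPECTED_COUNTS["L-AAOCA"]
        ):
            warnings.warn(
                f"cohort counts {counts} differ from the expected "
                f"{EXPECTED_COUNTS}; statistics computed on what was read",
                CohortIntegrityWarning,
                stacklevel=2,
            )
        return table

    @property
    def counts(self) -> dict:
        out = {"total": int(len(self.records))}
        out.update(
            {k: int(v) for k, v in
             self.records["anomaly_class"].value_counts().items()}
        )
        return out

    def subset(self, anomaly_class: str | None) -> pd.DataFrame:
        if anomaly_class is None:
            return self.records
        return self.records[self.records["anomaly_class"] == anomaly_class]


def load_cohort(path=None) -> CohortTable:
    """Load the packaged cohort fixture, or a user CSV with the same schema."""
    if path is not None:
        return CohortTable.from_csv(path)
    ref = resources.files("imlen").joinpath("data/table1.csv")
    with resources.as_file(ref) as p:
        return CohortTable.from_csv(p)


# ---------------------------------------------------------------------------
# agreement statistics
# ---------------------------------------------------------------------------

def rmse(estimates, reference) -> float:
    """Root-mean-square difference between paired measurements, mm."""
    est = np.asarray(estimates, dtype=np.float64)
    ref = np.asarray(reference, dtype=np.float64)
    if est.shape != ref.shape:
        raise ValueError("estimate and reference lengths differ")
    if est.size == 0:
        raise ValueError("empty input")
    return float(np.sqrt(np.mean((est - ref) ** 2)))


def error_summary(estimates, reference) -> tuple[float, float]:
    """Mean signed error and its sample (n-1) standard deviation, mm."""
    est = np.asarray(estimates, dtype=np.float64)
    ref = np.asarray(reference, dtype=np.float64)
    if est.shape != ref.shape:
        raise ValueError("estimate and reference lengths differ")
    if est.size < 2:
        raise ValueError("need at least 2 pairs for a sample SD")
    err = est - ref
    return float(err.mean()), float(err.std(ddof=1))


def _exact_signrank_cdf(double_ranks: np.ndarray) -> np.ndarray:
    """Counts of sign assignments per doubled rank-sum value.

    The distribution of W+ over all 2^n sign assignments of the ranked
    absolute differences (mid-ranks for ties, doubled so sums are
    integers), built by dynamic programming; equivalent to exhaustive
    enumeration of the 2^n sign vectors.
    """
    total = int(double_ranks.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in double_ranks:
        r = int(r)
        new = counts.copy()
        new[r:] += counts[: total + 1 - r]
        counts = new
    return counts


def wilcoxon_signed_rank(x, y, mode: str = "auto") -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test, two-sided.

    Zero differences are dropped and tied absolute differences mid-ranked
    (the classical procedure). ``mode="exact"`` enumerates the 2^n sign
    assignments of the ranks (via an equivalent dynamic program; n <= 25
    required); ``"approx"`` uses the normal approximation with tie and
    continuity corrections; ``"auto"`` picks exact for n <= 25.

    Returns ``(statistic, p)`` with the statistic min(W+, W-).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        raise ValueError("all paired differences are zero")
    if mode not in ("exact", "approx", "auto"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "auto":
        mode = "exact" if n <= 25 else "approx"
    if mode == "exact" and n > 25:
        raise ValueError(f"exact mode limited to n <= 25 pairs, got {n}")

    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    statistic = min(w_plus, w_minus)

    if mode == "exact":
        dbl = np.rint(2.0 * ranks).astype(np.int64)
        counts = _exact_signrank_cdf(dbl)
        total = counts.sum()  # 2**n
        w2 = int(round(2.0 * w_plus))
        p_le = counts[: w2 + 1].sum() / total
        p_ge = counts[w2:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
    else:
        mu = n * (n + 1) / 4.0
        _, t_counts = np.unique(ranks, return_counts=True)
        tie_corr = (t_counts**3 - t_counts).sum() / 48.0
        sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_corr)
        dev = w_plus - mu
        dev -= 0.5 * np.sign(dev)  # continuity correction
        z = dev / sigma
        p = float(2.0 * sps.norm.sf(abs(z)))
    return statistic, float(min(p, 1.0))


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def _group_stats(df: pd.DataFrame, wilcoxon_mode: str) -> dict:
    surg = df["surgical_mm"].to_numpy()
    comp = df["computational_mm"].to_numpy()
    rad = df["radiologic_mm"].to_numpy()
    mean_c, sd_c = error_summary(comp, surg)
    mean_r, sd_r = error_summary(rad, surg)
    out = {
        "n": int(len(df)),
        "rmse_computational_mm": rmse(comp, surg),
        "rmse_radiologic_mm": rmse(rad, surg),
        "mean_error_computational_mm": mean_c,
        "sd_error_computational_mm": sd_c,
        "mean_error_radiologic_mm": mean_r,
        "sd_error_radiologic_mm": sd_r,
    }
    try:
        stat, p = wilcoxon_signed_rank(comp, rad, mode=wilcoxon_mode)
        n_eff = int((comp - rad != 0).sum())
        out["wilcoxon"] = {
            "statistic": stat,
            "p_two_sided": p,
            "n_nonzero": n_eff,
            "mode": ("exact" if (wilcoxon_mode == "auto" and n_eff <= 25)
                     else "approx" if wilcoxon_mode == "auto" else wilcoxon_mode),
        }
    except ValueError as exc:
        out["wilcoxon"] = {"error": str(exc)}
    return out


def cohort_report(table: CohortTable, wilcoxon_mode: str = "auto") -> dict:
    """Full agreement report: counts plus per-cohort statistics."""
    report = {"counts": table.counts, "groups": {}}
    for name, cls in (("overall", None), ("L-AAOCA", "L-AAOCA"), ("R-AAOCA", "R-AAOCA")):
        sub = table.subset(cls)
        if len(sub):
            report["groups"][name] = _group_stats(sub, wilcoxon_mode)
    return report


def report_text(report: dict) -> str:
    """Human-readable rendering, 1 decimal place for mm values."""
    lines = []
    c = report["counts"]
    lines.append(
        f"Cohort: {c['total']} patients "
        f"({c.get('R-AAOCA', 0)} R-AAOCA, {c.get('L-AAOCA', 0)} L-AAOCA)"
    )
    for name, g in report["groups"].items():
        lines.append(f"\n{name} (n = {g['n']})")
        lines.append(
            f"  RMSE vs surgical:  computational {g['rmse_computational_mm']:.1f} mm, "
            f"radiologic {g['rmse_radiologic_mm']:.1f} mm"
        )
        lines.append(
            f"  Mean error (SD):   computational {g['mean_error_computational_mm']:.1f} "
            f"({g['sd_error_computational_mm']:.1f}) mm, "
            f"radiologic {g['mean_error_radiologic_mm']:.1f} "
            f"({g['sd_error_radiologic_mm']:.1f}) mm"
        )
        w = g.get("wilcoxon", {})
        if "p_two_sided" in w:
            lines.append(
                f"  Wilcoxon comp vs rad: W = {w['statistic']:.1f}, "
                f"p = {w['p_two_sided']:.3g} ({w['mode']}, n = {w['n_nonzero']})"
            )
    return "\n".join(lines) + "\n"


def report_to_json(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
        fh.write("\n")
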