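"""ROH-based inbreeding, bottleneck detection and founder-event dating.

Three pieces of machinery sit on top of a ROH sweep:

* the genomic inbreeding coefficient F_ROH>x = sum(L_ROH>x) / L_aut, with
  the autosome length L_aut = 2,881,033.286 kb (the summed GRCh37 autosome
  lengths), and the parental relatedness it implies, R_ROH>x = 2 F_ROH>x
  (the inbreeding coefficient of an individual equals the kinship of its
  parents when ancestors are not themselves inbred);

* a bottleneck/consanguinity detector on the NROH-versus-SROH plane: with
  both axes commensurate (SROH in Mb), points on the diagonal nroh =
  sroh_mb correspond to segments averaging 1 Mb; the signed vertical
  deviation d = sroh_mb - nroh per sample per minimum length x traces a
  founder event.  L_min is the smallest grid x at which every sample sits
  below/right of the diagonal (d > 0) and L_max the grid x maximising the
  median deviation across samples;

* a length-to-time conversion: IBD segments from a common ancestor g
  generations back are exponentially distributed with mean 100/(2g) cM, so
  g_hat = 100 / (2 L_cM); calendar time uses t = gen_time * g_hat years
  before a reference year (by default the cohort's average birth year).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .het_stats import summarize

#: GRCh37 autosome lengths (bp), as carried in the reference BAM headers.
GRCH37_AUTOSOME_BP: dict[int, int] = {
    1: 249250621, 2: 243199373, 3: 198022430, 4: 191154276, 5: 180915260,
    6: 171115067, 7: 159138663, 8: 146364022, 9: 141213431, 10: 135534747,
    11: 135006516, 12: 133851895, 13: 115169878, 14: 107349540,
    15: 102531392, 16: 90354753, 17: 81195210, 18: 78077248, 19: 59128983,
    20: 63025520, 21: 48129895, 22: 51304566,
}

#: Total autosome length in kb (sums to 2,881,033.286 kb).
AUTOSOME_LENGTH_KB: float = sum(GRCH37_AUTOSOME_BP.values()) / 1000.0


@dataclass(frozen=True)
class TimingConfig:
    """Length-to-time conversion constants.

    ``gen_time`` is the human generation time in years; ``ref_year`` the
    reference calendar year counted back from (1960 for a birth-year
    convention; 2012, the sampling year, shifts estimates ~52 years up);
    ``cm_per_mb`` the genetic-map density (1 cM/Mb by default).
    """

    gen_time: float = 26.9
    ref_year: float = 1960.0
    cm_per_mb: float = 1.0


@dataclass(frozen=True)
class TimingEstimate:
    """Generations / years / calendar year implied by a ROH length."""

    length_mb: float
    length_cm: float
    g_hat: float
    t_years: float
    calendar_year: float

    def as_dict(self) -> dict:
        return {
            "length_mb": self.length_mb, "length_cm": self.length_cm,
            "g_hat": self.g_hat, "t_years": self.t_years,
            "calendar_year": self.calendar_year,
        }


def inbreeding_from_sroh(sroh_kb: float, l_aut_kb: float = AUTOSOME_LENGTH_KB) -> float:
    """F_ROH from a total ROH length in kb: sum(L_ROH) / L_aut."""
    if sroh_kb < 0:
        raise ValueError("negative total ROH length")
    return sroh_kb / l_aut_kb


def f_roh(
    sweep: pd.DataFrame, x_mb: float, l_aut_kb: float = AUTOSOME_LENGTH_KB
) -> pd.DataFrame:
    """Per-sample F_ROH>x and R_ROH>x = 2 F_ROH>x at one grid minimum length.

    ``sweep`` is the output of :func:`faroh.roh_caller.sweep_roh`; ``x_mb``
    must be on its grid.  ``l_aut_kb`` defaults to the GRCh37 autosome
    length; pass the simulated genome length for synthetic cohorts.
    """
    x_kb = x_mb * 1000.0
    rows = sweep[np.isclose(sweep["min_kb"], x_kb)]
    if rows.empty:
        raise ValueError(f"x = {x_mb} Mb is not on the sweep grid")
    f = rows["sroh_kb"].to_numpy() / l_aut_kb
    return pd.DataFrame(
        {
            "sample_id": rows["sample_id"].to_numpy(),
            "x_mb": x_mb,
            "f_roh": f,
            "r_roh": 2.0 * f,
        }
    )


def match_r_to_roh(r_median: float, roh_medians: pd.DataFrame) -> float:
    """Grid minimum length x* whose median R_ROH>x best matches kinship R.

    ``roh_medians`` has columns ``x_mb`` and ``r_roh``; ties go to the
    smaller x.  A small x* indicates the observed relatedness is of
    evolutionary rather than recent familial origin.
    """
    if roh_medians.empty:
        raise ValueError("empty R_ROH table")
    t = roh_medians.sort_values("x_mb")
    gap = (t["r_roh"] - r_median).abs().to_numpy()
    return float(t["x_mb"].to_numpy()[int(np.argmin(gap))])


@dataclass
class DeviationProfile:
    """Signed diagonal deviations and the L_min / L_max summary.

    ``table`` has one row per (sample, x): d = sroh_mb - nroh.  ``l_min_mb``
    is the smallest window x with d > 0 for every sample (start of the
    bottleneck/consanguinity signal); ``l_max_mb`` the window x maximising
    the median of d (its peak).  Either is None, with a diagnostic, when the
    sign condition never holds.
    """

    table: pd.DataFrame
    l_min_mb: float | None
    l_max_mb: float | None
    per_sample_argmax: dict[str, float] = field(default_factory=dict)
    diagnostics: list[str] = field(default_factory=list)


def deviation_profile(
    sweep: pd.DataFrame, window_mb: tuple[float, float] | None = None
) -> DeviationProfile:
    """NROH-vs-SROH diagonal deviations across the sweep grid.

    ``window_mb`` restricts the grid to [x_lo, x_hi] (inclusive); the full
    sweep grid is used when omitted.
    """
    t = sweep.copy()
    t["x_mb"] = t["min_kb"] / 1000.0
    if window_mb is not None:
        lo, hi = window_mb
        t = t[(t["x_mb"] >= lo - 1e-9) & (t["x_mb"] <= hi + 1e-9)]
    if t.empty:
        raise ValueError("sweep does not cover the requested window")
    t["d"] = t["sroh_kb"] / 1000.0 - t["nroh"]

    by_x = t.groupby("x_mb")["d"]
    mins = by_x.min()
    medians = by_x.median()
    diagnostics: list[str] = []
    below = mins[mins > 0]
    l_min = float(below.index.min()) if not below.empty else None
    if l_min is None:
        diagnostics.append("no grid length with all samples below the diagonal")
    l_max = float(medians.idxmax()) if (medians > 0).any() else None
    if l_max is None:
        diagnostics.append("median deviation never positive")
    per_sample = {
        s: float(g.set_index("x_mb")["d"].idxmax())
        for s, g in t.groupby("sample_id")
    }
    return DeviationProfile(
        table=t[["sample_id", "x_mb", "nroh", "sroh_kb", "d"]].reset_index(drop=True),
        l_min_mb=l_min,
        l_max_mb=l_max,
        per_sample_argmax=per_sample,
        diagnostics=diagnostics,
    )


def date_length(length_mb: float, cfg: TimingConfig = TimingConfig()) -> TimingEstimate:
    """Convert a ROH length to generations and calendar time.

    g_hat = 100 / (2 L_cM); t = gen_time * g_hat years before ``ref_year``.
    """
    if length_mb <= 0:
        raise ValueError("length must be positive")
    length_cm = length_mb * cfg.cm_per_mb
    g_hat = 100.0 / (2.0 * length_cm)
    t_years = cfg.gen_time * g_hat
    return TimingEstimate(
        length_mb=length_mb,
        length_cm=length_cm,
        g_hat=g_hat,
        t_years=t_years,
        calendar_year=cfg.ref_year - t_years,
    )


REPORT_X_MB = (0.1, 1.5, 5.0)


def founder_report(
    sweep: pd.DataFrame,
    kinship_table: pd.DataFrame | None = None,
    sample_table: pd.DataFrame | None = None,
    cfg: TimingConfig = TimingConfig(),
    window_mb: tuple[float, float] | None = None,
) -> dict:
    """Assemble the cohort-level summary report as a JSON-serialisable dict.

    Contains median/iqr/mean/sd summaries of per-sample N_SNP and H (when
    ``sample_table`` is given), pairwise relatedness R (when
    ``kinship_table`` is given), NROH/SROH/AVROH/F_ROH/R_ROH at x in
    {0.1, 1.5, 5.0} Mb, and the deviation-profile dating under the
    configured reference year and the 2012 sampling-year alternative.
    """
    report: dict = {"roh": {}, "timing": {}}

    grid_mb = np.unique(sweep["min_kb"].to_numpy()) / 1000.0
    for x in REPORT_X_MB:
        if not np.isclose(grid_mb, x).any():
            continue
        rows = sweep[np.isclose(sweep["min_kb"], x * 1000.0)]
        fr = f_roh(sweep, x)
        report["roh"][f"x={x}"] = {
            "nroh": summarize(rows["nroh"]).as_dict(),
            "sroh_mb": summarize(rows["sroh_kb"] / 1000.0).as_dict(),
            "avroh_mb": summarize(
                rows["avroh_kb"].replace(0.0, np.nan).dropna() / 1000.0
                if (rows["nroh"] > 0).any()
                else rows["avroh_kb"] / 1000.0
            ).as_dict(),
            "f_roh": summarize(fr["f_roh"]).as_dict(),
            "r_roh": summarize(fr["r_roh"]).as_dict(),
        }

    if sample_table is not None:
        report["samples"] = {
            "n_snp": summarize(sample_table["n_snp"]).as_dict(),
            "het": summarize(sample_table["het"].dropna()).as_dict(),
        }
    if kinship_table is not None:
        r_vals = kinship_table["relatedness"].dropna()
        report["kinship"] = {"relatedness": summarize(r_vals).as_dict()}
        medians = pd.DataFrame(
            {
                "x_mb": [x for x in REPORT_X_MB if np.isclose(grid_mb, x).any()],
            }
        )
        medians["r_roh"] = [
            float(f_roh(sweep, x)["r_roh"].median()) for x in medians["x_mb"]
        ]
        report["kinship"]["matched_x_mb"] = match_r_to_roh(
            float(r_vals.median()), medians
        )

    prof = deviation_profile(sweep, window_mb)
    timing: dict = {"l_min_mb": prof.l_min_mb, "l_max_mb": prof.l_max_mb,
                    "diagnostics": prof.diagnostics}
    for label, ref_year in (("ref_year", cfg.ref_year), ("sampling_year", 2012.0)):
        cfg_alt = TimingConfig(cfg.gen_time, ref_year, cfg.cm_per_mb)
        for key, x in (("l_min", prof.l_min_mb), ("l_max", prof.l_max_mb)):
            timing[f"{key}_{label}"] = (
                date_length(x, cfg_alt).as_dict() if x else None
            )
    report["timing"] = timing
    return report


def write_report(report: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
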