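"""Group-mean outcome values reported by the five-patient clinical gait
study whose design the synthetic cohort emulates.

These printed group means (n = 5 patients, 3 trials each) are inputs for
the balanced paired-design identity: with complete data, the mean paired
difference between two conditions equals the difference of the condition
means, so the study's post-hoc mean-difference cells are recomputable from
this table alone.  Units: peak forces %BW, force impulses %BW*s, peak
moments %BW*BH, moment impulses %BW*BH*s.
"""

import pandas as pd

CONDITIONS = ("shod", "insole_0", "insole_5", "insole_10",
              "toe_in", "toe_out", "wide")

GROUP_MEANS = {
    "linear": pd.DataFrame(
        {
            "shod":      {"peak_kam": 3.44, "kam_impulse": 1.50, "peak_mcf": 240.50, "mcf_impulse": 115.07},
            "insole_0":  {"peak_kam": 3.39, "kam_impulse": 1.49, "peak_mcf": 239.06, "mcf_impulse": 114.23},
            "insole_5":  {"peak_kam": 3.39, "kam_impulse": 1.50, "peak_mcf": 237.40, "mcf_impulse": 114.08},
            "insole_10": {"peak_kam": 3.39, "kam_impulse": 1.53, "peak_mcf": 243.80, "mcf_impulse": 117.94},
            "toe_in":    {"peak_kam": 3.08, "kam_impulse": 1.38, "peak_mcf": 227.73, "mcf_impulse": 114.63},
            "toe_out":   {"peak_kam": 3.27, "kam_impulse": 1.52, "peak_mcf": 232.61, "mcf_impulse": 118.24},
            "wide":      {"peak_kam": 3.12, "kam_impulse": 1.38, "peak_mcf": 226.19, "mcf_impulse": 112.50},
        }
    ),
    "mri": pd.DataFrame(
        {
            "shod":      {"peak_kam": 2.92, "kam_impulse": 1.37, "peak_mcf": 234.21, "mcf_impulse": 114.59},
            "insole_0":  {"peak_kam": 2.87, "kam_impulse": 1.37, "peak_mcf": 233.11, "mcf_impulse": 114.19},
            "insole_5":  {"peak_kam": 2.94, "kam_impulse": 1.39, "peak_mcf": 237.25, "mcf_impulse": 116.71},
            "insole_10": {"peak_kam": 2.89, "kam_impulse": 1.39, "peak_mcf": 237.34, "mcf_impulse": 118.04},
            "toe_in":    {"peak_kam": 2.70, "kam_impulse": 1.26, "peak_mcf": 221.67, "mcf_impulse": 118.21},
            "toe_out":   {"peak_kam": 2.93, "kam_impulse": 1.41, "peak_mcf": 238.66, "mcf_impulse": 121.06},
            "wide":      {"peak_kam": 2.81, "kam_impulse": 1.28, "peak_mcf": 233.14, "mcf_impulse": 116.46},
        }
    ),
}


def mean_difference(model: str, metric: str, condition: str,
                    baseline: str = "shod") -> float:
    """Baseline-minus-condition difference of published group means."""
    tbl = GROUP_MEANS[model]
    return float(tbl.loc[metric, baseline] - tbl.loc[metric, condition])
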