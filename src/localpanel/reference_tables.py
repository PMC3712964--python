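"""Published per-MAF-bin imputation accuracies for two European isolates.

These are the reported leave-one-out mean dosage-r^2 values for the
Korčula (Adriatic island, Croatia) and Orkney (Scotland) cohorts, imputed
from ~300k-SNP array data against the 1000 Genomes panel alone
(``mean_r2_one``) and against 1000 Genomes plus a ~90-subject local exome
reference panel (``mean_r2_two``), in sqrt(10)-spaced MAF bins.  They serve
as inputs for the derived-cell arithmetic (per-bin r^2 increase and
effective-sample-size increase) in the worked example and the acceptance
script; nothing in the package fits to them.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["COHORT_BIN_MEANS", "cohort_reference_frame", "derive_cells"]

# cohort -> bin -> (n_snps, mean r^2 global-only, mean r^2 global+local)
COHORT_BIN_MEANS: dict[str, dict[str, tuple[int, float, float]]] = {
    "korcula": {
        "1-3.2%":  (12132, 0.504, 0.697),
        "3.2-10%": (11548, 0.729, 0.841),
        "10-32%":  (16243, 0.868, 0.916),
        ">32%":    (10174, 0.894, 0.934),
    },
    "orkney": {
        "1-3.2%":  (12123, 0.586, 0.753),
        "3.2-10%": (10677, 0.778, 0.867),
        "10-32%":  (15262, 0.894, 0.931),
        ">32%":    (9265, 0.913, 0.944),
    },
}


def cohort_reference_frame() -> pd.DataFrame:
    rows = [(cohort, b, n, one, two)
            for cohort, bins in COHORT_BIN_MEANS.items()
            for b, (n, one, two) in bins.items()]
    return pd.DataFrame(rows, columns=["cohort", "bin", "n_snps",
                                       "mean_r2_one", "mean_r2_two"])


def derive_cells() -> pd.DataFrame:
    """Derived cells from the per-panel means: r^2 increase and ESS increase.

    The effective-sample-size increase is the ratio of bin mean r^2 values
    minus one, in percent (rounded to a whole percent for reporting).
    """
    from .crossval import ess_increase

    df = cohort_reference_frame()
    df["increase_r2"] = df["mean_r2_two"] - df["mean_r2_one"]
    df["ess_increase_pct"] = [
        ess_increase(o, t) for o, t in zip(df["mean_r2_one"], df["mean_r2_two"])]
    return df
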