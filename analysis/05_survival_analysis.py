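#!/usr/bin/env python
"""Prognostic value of the signature stratification.

Kaplan-Meier curves and log-rank test for poor vs good prognosis,
multivariate Cox regression (cluster, INSS stage 4, MYCN amplification,
age >= 1 year), and the MYCN-normal subgroup rerun without the MYCN
covariate.  Survival rates are KM estimates at the 5-year horizon.
"""

import json
import warnings
from pathlib import Path

import pandas as pd

from hyposig.io import read_clinical_table
from hyposig.stratify import ClusterAssignment
from hyposig.survival import survival_report

DATA = Path("results/data")
STRAT = Path("results/stratification")
OUT = Path("results/survival")


def main() -> None:
    warnings.filterwarnings("ignore")
    OUT.mkdir(parents=True, exist_ok=True)
    clin = read_clinical_table(DATA / "clinical.csv")
    assign = pd.read_csv(STRAT / "assignment.csv", index_col=0)["cluster"]
    A = ClusterAssignment(list(assign.index), assign.to_numpy(), 0.0)
    prognosis = json.loads((STRAT / "prognosis.json").read_text())
    A.prognosis = {int(c): l for c, l in prognosis.items()}

    rep = survival_report(clin, A, horizon=5.0)
    (OUT / "survival_report.json").write_text(json.dumps(rep, indent=2, default=float))
    os_rep = rep["OS"]
    print(f"OS: 5-y survival {100 * os_rep['survival_rate_good']:.1f}% (good) vs "
          f"{100 * os_rep['survival_rate_poor']:.1f}% (poor), "
          f"log-rank p = {os_rep['logrank_p']:.2e}")
    cox = pd.DataFrame(os_rep["cox"]).T
    print("multivariate Cox (full cohort):")
    print(cox[["HR", "ci_lower", "ci_upper", "p"]].round(3).to_string())
    sub = rep["OS_mycn_normal"]
    print(f"MYCN-normal subgroup (n={sub['n']}): log-rank p = {sub['logrank_p']:.2e}")
    if "cox" in sub:
        subcox = pd.DataFrame(sub["cox"]).T
        print(subcox[["HR", "ci_lower", "ci_upper", "p"]].round(3).to_string())


if __name__ == "__main__":
    main()
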