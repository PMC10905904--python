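"""Convenience wiring of the analysis stages (used by the CLI and examples)."""

from __future__ import annotations

import pandas as pd

from . import core_io, metad_mle, sdt_type1

__all__ = ["subject_estimates", "condition_differences"]


def subject_estimates(trials) -> pd.DataFrame:
    """Type-1 and MLE meta-level estimates per subject x condition.

    ``trials`` is a list of TrialRecord or an equivalent DataFrame; fillers
    are excluded here.  Returns one row per subject x condition.
    """
    tables = core_io.tabulate_all(trials)
    rows = []
    for (sid, cond), table in tables.items():
        t1 = sdt_type1.compute_type1(table)
        fit = metad_mle.fit_meta_d(table, t1)
        rows.append(
            {
                "subject_id": sid,
                "condition": cond.value,
                "d_prime": t1.d_prime,
                "criterion_c": t1.criterion_c,
                "hit_rate": t1.hit_rate,
                "fa_rate": t1.fa_rate,
                "meta_d": fit.meta_d,
                "meta_c": fit.meta_c,
                "m_ratio": fit.m_ratio,
                "log_m_ratio": fit.log_m_ratio,
                "nll": fit.nll,
            }
        )
    return pd.DataFrame(rows).sort_values(["subject_id", "condition"]).reset_index(drop=True)


def condition_differences(estimates: pd.DataFrame,
                          measures=("d_prime", "criterion_c", "meta_c",
                                    "m_ratio", "log_m_ratio")) -> pd.DataFrame:
    """Depth-minus-control differences per subject for the given measures."""
    wide = estimates.pivot(index="subject_id", columns="condition")
    out = pd.DataFrame(index=wide.index)
    for m in measures:
        out[m] = wide[(m, "depth")] - wide[(m, "control")]
    return out.reset_index()
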