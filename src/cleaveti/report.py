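"""Result rendering: parenthetical-uncertainty tables for SFE results."""

from __future__ import annotations

import math

import pandas as pd

from .ti import TIResult


def format_uncertain(value: float, err: float) -> str:
    """Render ``value ± err`` in last-digit parenthetical style, e.g. 112.2(1).

    The uncertainty is rounded to one significant digit and the value to the
    matching decimal place.  Zero uncertainty renders the bare value.
    """
    if err < 0:
        raise ValueError("uncertainty must be non-negative")
    if err == 0:
        return f"{value:g}"
    exponent = math.floor(math.log10(err))
    digit = round(err / 10 ** exponent)
    if digit == 10:  # e.g. err = 0.096 -> 0.1
        digit, exponent = 1, exponent + 1
    if exponent >= 0:
        scale = 10 ** exponent
        return f"{round(value / scale) * scale:.0f}({digit * scale:.0f})"
    decimals = -exponent
    return f"{value:.{decimals}f}({digit})"


def sfe_row(label: str, result: TIResult) -> str:
    assert abs(result.gamma - (result.gamma_lj + result.gamma_c)) < 1e-9, \
        "component/total mismatch"
    return "\t".join([
        label,
        format_uncertain(result.gamma_lj, result.err_lj),
        format_uncertain(result.gamma_c, result.err_c),
        format_uncertain(result.gamma, result.err_total),
    ])


def sfe_table(rows: list[tuple[str, TIResult]]) -> str:
    """Human-readable summary table: orientation, γ^LJ, γ^C, γ."""
    lines = ["orientation\tgamma_LJ\tgamma_C\tgamma"]
    lines += [sfe_row(label, res) for label, res in rows]
    return "\n".join(lines)


def sfe_frame(rows: list[tuple[str, TIResult]]) -> pd.DataFrame:
    """Machine-readable summary of the same table."""
    return pd.DataFrame([
        {"orientation": label,
         "gamma_LJ": res.gamma_lj, "err_LJ": res.err_lj,
         "gamma_C": res.gamma_c, "err_C": res.err_c,
         "gamma": res.gamma, "err": res.err_total}
        for label, res in rows
    ])
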