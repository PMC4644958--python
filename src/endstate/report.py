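"""TSV rendering of compound energy tables and hydrogen-bond statistics.

Numbers are rendered at two decimals (round-half-even, Python's default
float formatting); re-parsing a rendered table reproduces the values at
rendered precision. Compounds without an experimental value render "null".
"""

from __future__ import annotations

import io as _io

import pandas as pd

from .mmgbsa import ALL_ROWS, DISPLAY_LABELS, AggregateResult, CompoundTable

_ROW_ORDER = list(ALL_ROWS) + ["exp"]


def _fmt(v: float | None) -> str:
    if v is None:
        return "null"
    return f"{v:.2f}"


def render_energy_table(table: CompoundTable) -> str:
    """Render a CompoundTable as TSV: one row per component, mean and sem
    sub-columns per compound."""
    if len(table) == 0:
        raise ValueError("empty compound table")
    out = _io.StringIO()
    header = ["Item"]
    for label in table.labels:
        header += [f"{label}_mean", f"{label}_sem"]
    out.write("\t".join(header) + "\n")
    for key in _ROW_ORDER:
        cells = [DISPLAY_LABELS[key]]
        any_value = False
        for label in table.labels:
            res = table[label]
            if key == "exp":
                mean, sem = res.exp, None
            else:
                mean = res.mean.get(key)
                sem = res.sem.get(key)
            if mean is not None:
                any_value = True
            cells.append(_fmt(mean))
            cells.append(_fmt(sem) if key != "exp" else "")
        if any_value:
            out.write("\t".join(cells) + "\n")
    return out.getvalue()


def parse_energy_table(text: str) -> CompoundTable:
    """Inverse of :func:`render_energy_table` at rendered (2 dp) precision."""
    df = pd.read_csv(_io.StringIO(text), sep="\t", index_col=0,
                     keep_default_na=False)
    labels = [c[:-5] for c in df.columns if c.endswith("_mean")]
    inverse = {v: k for k, v in DISPLAY_LABELS.items()}
    table = CompoundTable()
    for label in labels:
        mean: dict[str, float] = {}
        sem: dict[str, float] = {}
        exp = None
        for display, row in df.iterrows():
            key = inverse[display]
            raw = str(row[f"{label}_mean"]).strip()
            if raw in ("null", "", "nan"):
                continue
            val = float(raw)
            if key == "exp":
                exp = val
                continue
            mean[key] = val
            sraw = row[f"{label}_sem"]
            try:
                sem[key] = float(sraw)
            except (TypeError, ValueError):
                pass
        # recompute composites so rounded components keep identities exact
        if all(k in mean for k in ("e_ele", "e_vdw", "g_pol", "g_nonpol")):
            mean["g_ele_pol"] = mean["e_ele"] + mean["g_pol"]
            mean["g_vdw_nonpol"] = mean["e_vdw"] + mean["g_nonpol"]
            mean["h"] = sum(
                mean[k] for k in ("e_ele", "e_vdw", "g_pol", "g_nonpol")
            )
            if "neg_t_ds" in mean:
                mean["g_bind"] = mean["h"] + mean["neg_t_ds"]
        table.add(
            label,
            AggregateResult(mean=mean, sem=sem, n_snapshots=0, exp=exp),
        )
    return table


def render_hbond_table(stats) -> str:
    """Render hydrogen-bond occupancy statistics as TSV
    (donor, acceptor, Occ %, Dis Å)."""
    lines = ["donor\tacceptor\tOcc\tDis"]
    for s in stats:
        lines.append(
            f"{s.donor_label}\t{s.acceptor_label}\t{s.occupancy:.1f}\t"
            f"{s.mean_distance:.2f}"
        )
    return "\n".join(lines) + "\n"
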