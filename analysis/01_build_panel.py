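#!/usr/bin/env python
"""Build the multiplexed scheduled-MRM transition list.

Constructs the default 84-analyte panel (10 ganglioside classes in
negative mode, 4 neutral glycosphingolipid classes in positive mode,
plus 4 internal standards), reports its composition, and writes the
transition list in both the native and Skyline-style dialects.
"""

from pathlib import Path

from gslmrm.panel import (
    build_panel,
    default_panel_config,
    write_skyline_transition_list,
    write_transition_list,
)

OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    OUT.mkdir(exist_ok=True)
    cfg = default_panel_config()
    panel = build_panel(cfg)
    analytes = [t for t in panel if t.role == "analyte"]
    neg = [t for t in analytes if t.polarity == "negative"]
    pos = [t for t in analytes if t.polarity == "positive"]

    write_transition_list(panel, OUT / "transition_list.csv")
    write_skyline_transition_list(panel, OUT / "transition_list_skyline.csv")

    print(f"panel: {len(analytes)} analyte transitions "
          f"({len(neg)} negative over {len({t.class_name for t in neg})} classes, "
          f"{len(pos)} positive over {len({t.class_name for t in pos})} classes), "
          f"{len(panel) - len(analytes)} internal standards")
    rts = sorted(t.rt_min for t in panel)
    print(f"scheduled windows: 1.0 min wide, centres {rts[0]:.2f}-{rts[-1]:.2f} min "
          f"inside the 15-min gradient")
    gm3 = next(t for t in analytes if t.species_id == "GM3 d36:1")
    print(f"example transition: {gm3.species_id}  {gm3.precursor_mz:.4f} -> "
          f"{gm3.product_mz:.4f} ({gm3.precursor_charge:+d}, RT {gm3.rt_min} min)")
    print(f"wrote {OUT / 'transition_list.csv'} and Skyline-style export")


if __name__ == "__main__":
    main()
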