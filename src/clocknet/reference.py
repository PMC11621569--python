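"""Reference census of clock neurons identified in the FlyWire whole-brain
connectome, keyed by (clock class, clock cell type) with observed counts.

This is the published classification of the fly circadian network: four
dorsal-neuron classes (DN_1a, DN_1p, DN_2, DN_3) and four lateral-neuron
classes (LPN, LN_d, LN_ITP, LN_v_PDF), subdivided into cell types.  The
observed counts sum to 242 neurons, with 171 DN_3 of which 157 are the small
central-projecting subtypes (s-CPDN_3_A–E) — considerably more than the
~152 neurons expected from classical marker expression.
"""

from __future__ import annotations

from .roster import ClockRoster

# (clock_class, clock_cell_type) -> observed neuron count.
REFERENCE_OBSERVED_COUNTS: dict[tuple[str, str], int] = {
    ("DN_1a", "DN_1a"): 4,
    ("DN_1p", "DN_1p_A"): 8,
    ("DN_1p", "DN_1p_B"): 4,
    ("DN_1p", "DN_1p_C"): 4,
    ("DN_1p", "DN_1p_D"): 8,
    ("DN_1p", "DN_1p_E"): 4,
    ("DN_2", "DN_2"): 3,
    ("DN_3", "s-CPDN_3_A"): 38,
    ("DN_3", "s-CPDN_3_B"): 25,
    ("DN_3", "s-CPDN_3_C"): 32,
    ("DN_3", "s-CPDN_3_D"): 37,
    ("DN_3", "s-CPDN_3_E"): 25,
    ("DN_3", "l-CPDN_3"): 2,
    ("DN_3", "APDN_3"): 12,
    ("LPN", "LPN"): 6,
    ("LN_d", "LN_d_CRY-"): 6,
    ("LN_d", "LN_d_CRY+"): 4,
    ("LN_ITP", "LN_d_CRY+_ITP"): 2,
    ("LN_ITP", "5th-LN_v"): 2,
    ("LN_v_PDF", "l-LN_v"): 8,
    ("LN_v_PDF", "s-LN_v"): 8,
}


def reference_roster() -> ClockRoster:
    """Expand the observed per-cell-type counts into a roster with synthetic
    neuron ids (one id per counted neuron)."""
    membership = {}
    for (clock_class, cell_type), count in REFERENCE_OBSERVED_COUNTS.items():
        for k in range(count):
            membership[f"{cell_type}#{k:03d}"] = (clock_class, cell_type)
    return ClockRoster(membership)
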