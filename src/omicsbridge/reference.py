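"""Published reference values for the glycan–SPM screen.

The ten reported significant IgG-glycan / SPM pairwise associations
(standardized effect, SE, p-value, BH-FDR over the full 24 × 14 = 336-test
grid at N = 368).  These printed values are used as fixed inputs to check
the FDR arithmetic; the underlying cohort data is access-restricted, so the
effect sizes themselves are behavioral references, not recomputable targets.
"""

from __future__ import annotations

#: (glycan peak, SPM, standardized effect, SE, p-value, printed FDR)
REFERENCE_ASSOCIATIONS: list[tuple[str, str, float, float, float, float]] = [
    ("GP21", "5-HEPE", 0.32, 0.05, 4.4e-10, 1.5e-7),
    ("GP21", "EPA", 0.30, 0.05, 2.2e-8, 3.6e-6),
    ("GP21", "18-HEPE", 0.19, 0.05, 2.1e-4, 1.2e-2),
    ("GP20", "EPA", 0.28, 0.05, 1.3e-7, 1.4e-5),
    ("GP20", "5-HEPE", 0.24, 0.05, 1.5e-6, 1.2e-4),
    ("GP17", "EPA", 0.19, 0.05, 1.1e-3, 3.6e-2),
    ("GP17", "5-HEPE", 0.20, 0.05, 2.2e-4, 1.2e-2),
    ("GP9", "EPA", 0.20, 0.05, 2.6e-4, 1.3e-2),
    ("GP5", "EPA", 0.19, 0.05, 7.8e-4, 3.3e-2),
    ("GP4", "5-HEPE", -0.17, 0.05, 1.1e-3, 3.6e-2),
]

#: full screen size: 24 glycan peaks × 14 SPMs
REFERENCE_M_TOTAL = 336

REFERENCE_P_VALUES = [r[4] for r in REFERENCE_ASSOCIATIONS]
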