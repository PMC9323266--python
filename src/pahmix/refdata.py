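"""Reference datasets: fitted microsomal kinetic parameters for BaP and DBC,
their mutual competitive-inhibition constants, and the Supermix-10 mixture
composition (the ten most abundant PAHs at the Portland Harbor Superfund
site, molar ratios normalized to 2-methylnaphthalene).
"""

from __future__ import annotations

from .inhibition import MixtureComponent, MixtureComposition
from .kinetics import KineticModelSpec, ModelForm

__all__ = [
    "MOLECULAR_WEIGHT",
    "MICROSOMAL_BASELINE",
    "INHIBITION_KI_UM",
    "INHIBITION_SUBSTRATE_CONC_UM",
    "SUPERMIX10",
]

MOLECULAR_WEIGHT = {"BaP": 252.31, "DBC": 302.37}  # g/mol

# Michaelis–Menten-clearance fits to human-liver-microsome depletion rates:
# vmax1 nmol/min/mg, km1 µM, clint2 mL/min/mg.
MICROSOMAL_BASELINE = {
    "BaP": KineticModelSpec(ModelForm.MM_CLEARANCE, vmax1=0.0063, km1=0.088, clint2=0.0012),
    "DBC": KineticModelSpec(ModelForm.MM_CLEARANCE, vmax1=0.00090, km1=0.060, clint2=0.0017),
}

# Apparent competitive Ki (µM) keyed (substrate, inhibitor): the inhibitor
# shifts the substrate's high-affinity-phase Km1.
INHIBITION_KI_UM = {
    ("BaP", "DBC"): 0.44,
    ("BaP", "Supermix-10"): 0.75,
    ("DBC", "BaP"): 0.061,
    ("DBC", "Supermix-10"): 0.63,
}

# Nominal substrate concentrations (µM) used in the inhibition assays.
INHIBITION_SUBSTRATE_CONC_UM = {"BaP": 0.14, "DBC": 0.17}

SUPERMIX10 = MixtureComposition(
    components=(
        MixtureComponent("benzo(a)anthracene", "56-55-3", 228.29, 2.47),
        MixtureComponent("retene", "483-65-8", 234.34, 7.43),
        MixtureComponent("pyrene", "129-00-0", 202.25, 14.50),
        MixtureComponent("phenanthrene", "85-01-8", 178.23, 1.72),
        MixtureComponent("naphthalene", "91-20-3", 128.17, 3.48),
        MixtureComponent("fluorene", "86-73-7", 166.22, 1.84),
        MixtureComponent("fluoranthene", "206-44-0", 202.25, 14.24),
        MixtureComponent("chrysene", "218-01-9", 228.29, 2.59),
        MixtureComponent("acenaphthylene", "208-96-8", 154.21, 2.00),
        MixtureComponent("2-methylnaphthalene", "91-57-6", 142.20, 1.00),
    )
)
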