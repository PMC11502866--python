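"""Published summary statistics used as preset parameters and anchors.

These are the printed per-group (mean, SD, n) values from the source
study's figure legends and methods; they parameterize the population
simulator and the worked examples.  They are inputs, not results computed
by this package.
"""

from .core import GroupSummary

#: 3D cilium length by cell type (um), unpaired two-tailed t-test groups.
CILIA_LENGTH_GROUPS = (
    GroupSummary("ductal", 12.41, 2.8, 21, units="um"),
    GroupSummary("non_beta", 6.610, 1.158, 22, units="um"),
    GroupSummary("beta", 6.804, 1.841, 42, units="um"),
)

#: Percent ciliation by cell type across 3 islets from 3 mice (50 cells/islet).
CILIATION_GROUPS = (
    GroupSummary("beta", 85.3, 1.528, 3, units="percent"),
    GroupSummary("non_beta", 80.0, 6.557, 3, units="percent"),
)

#: Axoneme tubule lengths from the fully reconstructed cilia (nm).
MOUSE_A_TUBULE_NM = GroupSummary("mouse_A", 4570.0, 140.0, 9, units="nm")
MOUSE_B_TUBULE_NM = GroupSummary("mouse_B", 3030.0, 1010.0, 9, units="nm")
HUMAN_A_TUBULE_NM = GroupSummary("human_A", 2050.0, 1010.0, 9, units="nm")
HUMAN_B_TUBULE_NM = GroupSummary("human_B", 1200.0, 650.0, 9, units="nm")

#: Membrane-distance levels of peripheral vs displaced doublets (nm).
BASELINE_MEMBRANE_DISTANCE_NM = 40.0
DISPLACED_MEMBRANE_DISTANCE_NM = 100.0

#: Whole-cilium lengths in the volume-EM reconstructions (nm).
MOUSE_CILIUM_LENGTH_NM = 4200.0
HUMAN_CILIUM_LENGTH_NM = 2700.0

#: Contact fractions (percent, mean +/- SD across animals).
AXON_CONTACT_FRACTION = GroupSummary("axon_contact", 12.5, 2.8, 2, units="percent")
SYNAPSIN1_POSITIVE_FRACTION = GroupSummary("synapsin1", 70.8, 3.7, 2, units="percent")
VACHT_POSITIVE_FRACTION = GroupSummary("vacht", 64.2, 27.7, 2, units="percent")

#: Confocal screening scale behind the contact fractions.
N_CILIA_SCREENED = 1700
N_ISLETS_SCREENED = 24

#: U-ExM calibration worked example: measured ruler width (nm) -> factor ~4.3.
RULER_EXAMPLE_WIDTH_NM = 968.0
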