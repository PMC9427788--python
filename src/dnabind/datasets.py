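"""Published reference values for the palbociclib / calf-thymus-DNA system.

Palbociclib (a CDK4/6 inhibitor) binding to CT-DNA is the worked example
this package ships: the published study reports Benesi-Hildebrand binding
constants at four temperatures (raw titrations are not deposited). Those
printed constants are inputs for the thermodynamic analysis and the
worked examples; nothing here is a fitted output of this package.
"""

from .thermo import KbSeries

#: Published binding constants Kb(T) of the palbociclib-CT-DNA complex,
#: (temperature K, Kb M^-1), reported to three significant figures.
PALBOCICLIB_CTDNA_KB = KbSeries(
    entries=((298.0, 6.42e3), (303.0, 6.26e3), (308.0, 6.16e3), (313.0, 6.01e3)),
    source="published palbociclib/CT-DNA UV-Vis titration study",
)

#: A260/A280 ratio reported for the CT-DNA preparation used in that study.
PALBOCICLIB_STUDY_PURITY_RATIO = 1.903

#: Working CT-DNA concentration (mol nucleotide / L) of that study.
PALBOCICLIB_STUDY_DNA_CONC = 8.25e-5
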