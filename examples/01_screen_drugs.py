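"""Screen a handful of drugs against the builtin structural-alert library.

Builds three reference molecules — aniline (the archetypal aromatic-amine
alert carrier), toluene (its alert-free control) and benzene — and prints
which alerts each one matches. A True in the aromatic-amine columns marks a
molecule that could be bioactivated into a protein-reactive metabolite.
"""

from adalert import builtin_alerts, screen_library
from adalert.screening import ADLabel, DrugRecord

drugs = [
    DrugRecord("aniline", "aniline", "Nc1ccccc1", 150.0, ADLabel.AD_POSITIVE),
    DrugRecord("toluene", "toluene", "Cc1ccccc1", 50.0, ADLabel.AD_NEGATIVE),
    DrugRecord("benzene", "benzene", "c1ccccc1", 200.0, ADLabel.AD_NEGATIVE),
]

library = builtin_alerts()
matrix = screen_library(drugs, library)

frame = matrix.to_frame()
print(frame.T)  # rows = alerts, columns = drugs; 1 = substructure present
print()
print("aniline alert hits:", [a for a in frame.columns if False] or
      list(frame.columns[frame.loc["aniline"] == 1]))
# aniline lights up the aromatic-amine family (plus the decomposed nitrogen
# and benzene patterns); toluene and benzene match no nitrogen alert.
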