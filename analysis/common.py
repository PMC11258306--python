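"""Shared paths and the study-wide seed for the analysis drivers."""

from pathlib import Path

REPO = Path(__file__).resolve().parent.parent
DATA = REPO / "results" / "analysis" / "data"
OUT = REPO / "results" / "analysis"
SEED = 11

#: generative pattern counts for the simulated cohort: proportions follow the
#: annotated ROI mix of a mixed-histotype ovarian carcinoma cohort
#: (roughly one third each diffuse / focal, and a slightly larger
#: insignificant fraction), scaled down for a desk-sized run
PATTERN_COUNTS = {"diffuse": 14, "focal": 12, "insignificant": 14}
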