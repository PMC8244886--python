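"""Compute diversity metrics for the shipped model networks.

Realizes each model-network fixture as a sequence alignment, runs the full
pipeline, and prints one row per network. Hd is the probability that two
randomly drawn individuals carry different haplotypes; Bd the probability
they fall in different haplotype classes (degree groups); HBd combines both
into a single network-complexity value.
"""

from hapnetdiv import compute_report, panel_fixtures, realize

print(f"{'dataset':<16}{'n':>4}{'nH':>4}{'nHc':>5}{'Hd':>7}{'Bd':>7}{'HBd':>7}{'Nd':>7}")
for name, spec in panel_fixtures().items():
    r = compute_report(realize(spec), dataset=name)
    print(
        f"{name:<16}{r.n:>4}{r.nH:>4}{r.nHc:>5}"
        f"{r.Hd:>7.2f}{r.Bd:>7.2f}{r.HBd:>7.2f}{r.Nd:>7.2f}"
    )
print(
    "\nfig1A and fig1B share Hd=0.86 (same haplotype frequencies) but differ "
    "in Bd/HBd:\ntopology alone separates the two networks."
)
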