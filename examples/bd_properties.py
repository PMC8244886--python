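"""Sweep the structural properties of branch diversity (Bd).

Bd applies the Nei diversity construction to haplotype-class frequencies,
so it (1) grows with the number of classes, approaching (1-1/nHc)*n/(n-1)
for even splits, (2) is maximized by even class sizes, and (3) decays
toward the uncorrected 1 - sum(f^2) as the sample grows at fixed
proportions.
"""

from hapnetdiv import hd  # Bd is the same construction on class counts

n = 48
print("classes sweep (n=48, even splits):")
for n_classes in (1, 2, 3, 4, 6, 8, 12):
    per = n // n_classes
    counts = [per] * n_classes
    print(f"  nHc={n_classes:>2}  Bd={hd(counts):.4f}")

print("\nevenness sweep (n=48, 2 classes):")
for split in ([24, 24], [30, 18], [40, 8], [46, 2]):
    print(f"  niHc={split}  Bd={hd(split):.4f}")

print("\nsample-size sweep (two even classes):")
for m in (5, 10, 100, 10_000):
    print(f"  n={2 * m:>6}  Bd={hd([m, m]):.6f}")
print("\nBd -> 0.5 from above as n grows: the n/(n-1) correction vanishes.")
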