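"""In-silico tryptic digestion and peptide physical chemistry.

Digests a small protein, then scores each peptide's hydropathy (GRAVY)
and isoelectric point (pI). Positive GRAVY means hydrophobic; pI is the
pH of zero net charge under the IPC_peptide pKa set.
"""

from paleoqc import ProteinRecord, digest, gravy, isoelectric_point

protein = ProteinRecord(
    "DEMO1", "demo membrane-like protein",
    "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQVKVK",
)

print(f"{'peptide':<22}{'missed':>7}{'GRAVY':>8}{'pI':>7}")
for pep in digest(protein, max_missed=1, min_len=6, max_len=30):
    print(
        f"{pep.sequence:<22}{pep.missed_cleavages:>7}"
        f"{gravy(pep.sequence):>8.2f}{isoelectric_point(pep.sequence):>7.2f}"
    )
# Each row is one tryptic peptide with up to one retained (missed) K/R
# site; GRAVY > 0 flags peptides likely to behave hydrophobically in
# extraction, and low pI flags acidic peptides.
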