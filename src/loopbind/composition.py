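"""Molecular-mass bookkeeping for the stoichiometry (light-scattering) check.

A 1:1 protein/RNA complex has a theoretical mass equal to the sum of the
average masses of its two chains.  The tandem-RRM fragment sequence (hnRNP A1
residues 1-196, identical in both splice isoforms over this range) is
embedded below; masses are computed with Biopython's average atomic weights.
"""

from __future__ import annotations

from Bio.SeqUtils import molecular_weight

__all__ = ["UP1_SEQUENCE", "RNA_12MER", "protein_average_mass", "rna_average_mass",
           "complex_mass_kda"]

#: hnRNP A1 residues 1-196 (the UP1 fragment), UniProt P09651.
UP1_SEQUENCE = (
    "MSKSESPKEPEQLRKLFIGGLSFETTDESLRSHFEQWGTLTDCVVMRDPN"
    "TKRSRGFGFVTYATVEEVDAAMNARPHKVDGRVVEPKRAVSREDSQRPGA"
    "HLTVKKIFVGGIKEDTEEHHLRDYFEQYGKIEVIEIMTDRGSGKKRGFAF"
    "VTFDDHDSVDKIVIQKYHTVNGHNCEVRKALSKQEMASASSSQRGR"
)

#: the high-affinity single-stranded recognition element
RNA_12MER = "AGUAGAUUAGCA"


def protein_average_mass(sequence: str = UP1_SEQUENCE) -> float:
    """Average mass (Da) of an unmodified linear peptide."""
    return molecular_weight(sequence, seq_type="protein")


def rna_average_mass(sequence: str = RNA_12MER, five_prime_phosphate: bool = False) -> float:
    """Average mass (Da) of a linear RNA; synthetic oligos carry a 5'-OH."""
    mass = molecular_weight(sequence, seq_type="RNA")
    if not five_prime_phosphate:
        mass -= 79.98      # remove the HPO3 of the 5'-monophosphate convention
    return mass


def complex_mass_kda(protein_seq: str = UP1_SEQUENCE, rna_seq: str = RNA_12MER) -> float:
    """Theoretical 1:1 complex mass in kDa."""
    return (protein_average_mass(protein_seq) + rna_average_mass(rna_seq)) / 1000.0
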