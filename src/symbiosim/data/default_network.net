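# Curated metabolic-MAPK regulatory network.
#
# Environment-driven inputs (substance, activation threshold; oxygen in %O2,
# glucose and lactate in mM, TGFA in arbitrary units).  An input node is
# active iff the local concentration is >= its threshold.
input Oxygen_supply  @ oxygen  >= 1.5
input Glucose_supply @ glucose >= 1.2
input Lactate_supply @ lactate >= 0.8
input EGFR_stimulus  @ tgfa    >= 1e-6
input DNA_damage                       # unbound; set by perturbation only

# Drug-driven inhibitor inputs (activated stochastically by the therapy layer).
inhibitor GLUT1I
inhibitor MCT1I
inhibitor MCT4I

# Growth-factor signalling cascade.
EGFR := EGFR_stimulus
ERK  := EGFR
MYC  := ERK

# p14ARF / MDM2 / p53 axis: oncogenic MYC stress induces p14, which blocks
# MDM2-mediated p53 inactivation, so p53 is active in wild-type tumour cells.
p14  := MYC
MDM2 := ERK AND NOT p14
p53  := NOT MDM2

# Hypoxia response and the Warburg switch: HIF1 under hypoxia; PDK (pyruvate
# dehydrogenase kinase, HIF/MYC driven) diverts pyruvate away from the
# mitochondria, suppressing glucose-fuelled OXPHOS in signalling-active cells.
HIF1 := NOT Oxygen_supply
PDK  := HIF1 OR MYC

# Transporters.  p53 loss de-represses GLUT1; MCT1 imports lactate; MCT4
# exports lactate whenever the cell runs glycolysis.
GLUT1 := (MYC OR HIF1 OR NOT p53) AND NOT GLUT1I
MCT1  := NOT MCT1I
MCT4  := glycoATP AND NOT MCT4I

# MCT1-dependent lactate-intake branch: exogenous lactate oxidised under
# oxygen (reverse Warburg).  This node defines "lactate-metabolic" cells.
Lactate_oxidation := Oxygen_supply AND Lactate_supply AND MCT1

# Metabolic pathway bits read by the stoichiometric layer.  Oxygenated cells
# prefer lactate oxidation over glycolysis; hypoxic cells always glycolyse.
glycoATP := Glucose_supply AND GLUT1 AND (HIF1 OR NOT Lactate_oxidation)
mitoATP  := Oxygen_supply AND (Lactate_oxidation OR (Glucose_supply AND GLUT1 AND NOT PDK))

# Energy stress: no usable carbon source — glucose entry blocked or absent,
# and no oxidisable exogenous lactate.  (Defined over supply and transporter
# nodes, which are stable within a phenotype step, rather than the ATP bits,
# so a pathway switch in mid-sweep cannot masquerade as starvation.)
Starvation := NOT (Glucose_supply AND GLUT1) AND NOT Lactate_oxidation

# Fate outputs.
Apoptosis     := p53 AND (DNA_damage OR Starvation)
Proliferation := (glycoATP OR mitoATP) AND NOT Apoptosis
Growth_Arrest := NOT Proliferation AND NOT Apoptosis
Necrosis      := NOT Oxygen_supply AND NOT Glucose_supply
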