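# Drug-gene actionability rules. A rule triggers when the sample's phenotype
# class for `gene` is in `phenotypes`. Category 2 = dosing/selection guidance
# would benefit the patient; category 3 = variant associated with a serious or
# life-threatening adverse response. Category 1 is the absence of any trigger.
# Specialty tags come from a closed vocabulary (see panel module).
CYP2D6:
  - phenotypes: [poor, intermediate]
    category: 2
    drugs: [aripiprazole, atomoxetine, desipramine, duloxetine, fluvoxamine,
            haloperidol, nortriptyline, paroxetine, venlafaxine, amitriptyline,
            flecainide, propafenone, tamoxifen]
    specialties: [psychiatry, pain, cardiology, oncology]
    source: CPIC
  - phenotypes: [ultrarapid]
    category: 3
    drugs: [codeine, tramadol, oxycodone]
    specialties: [pain]
    source: CPIC
CYP2C19:
  - phenotypes: [poor, intermediate, ultrarapid]
    category: 2
    drugs: [citalopram, escitalopram, sertraline, clomipramine, doxepin,
            imipramine, trimipramine, clopidogrel, esomeprazole, lansoprazole,
            omeprazole, pantoprazole]
    specialties: [psychiatry, cardiology, neurology, gastroenterology]
    source: CPIC
CYP2C9:
  - phenotypes: [poor, intermediate]
    category: 2
    drugs: [warfarin]
    specialties: [cardiology, neurology]
    source: CPIC
VKORC1:
  - phenotypes: [decreased_function]
    category: 2
    drugs: [warfarin]
    specialties: [cardiology, neurology]
    source: CPIC
SLCO1B1:
  - phenotypes: [decreased_function]
    category: 2
    drugs: [simvastatin]
    specialties: [cardiology]
    source: CPIC
HLA-A:
  - phenotypes: [carrier]
    category: 3
    drugs: [carbamazepine]
    specialties: [neurology, psychiatry, pain]
    source: CPIC
HLA-B:
  - phenotypes: [carrier]
    category: 3
    drugs: [abacavir]
    specialties: [infectious_diseases]
    source: CPIC
IFNL3:
  - phenotypes: [decreased_function]
    category: 2
    drugs: [boceprevir, peginterferon, ribavirin, telaprevir]
    specialties: [infectious_diseases]
    source: CPIC
TPMT:
  - phenotypes: [poor]
    category: 3
    drugs: [azathioprine, mercaptopurine, thioguanine]
    specialties: [gastroenterology, oncology, transplant]
    source: CPIC
  - phenotypes: [intermediate]
    category: 2
    drugs: [azathioprine, mercaptopurine, thioguanine]
    specialties: [gastroenterology, oncology, transplant]
    source: CPIC
DPYD:
  - phenotypes: [poor]
    category: 3
    drugs: [capecitabine, fluorouracil, tegafur]
    specialties: [oncology]
    source: CPIC
  - phenotypes: [intermediate]
    category: 2
    drugs: [capecitabine, fluorouracil, tegafur]
    specialties: [oncology]
    source: CPIC
CYP3A5:
  - phenotypes: [extensive, intermediate]
    category: 2
    drugs: [tacrolimus]
    specialties: [transplant]
    source: CPIC
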