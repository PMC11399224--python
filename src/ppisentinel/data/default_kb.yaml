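# Default drug-class knowledge base.
#
# ATC codes or prefixes; the longest matching prefix wins. The therapeutic
# anticoagulation thresholds and the low-dose aspirin cut-off encode local
# clinical consensus, not guideline constants: review them before use
# against real data. SSRIs are the packaged "drugs associated with
# gastrointestinal bleeding"; the class list may be extended here.
version: "1.0.0"

classes:
  # non-selective NSAIDs (anti-inflammatory, non-steroid)
  M01A: NSAID
  # selective COX-2 inhibitors refine the NSAID prefix
  M01AH: COX2
  # antiplatelet agents; aspirin gets its own dose-dependent entry
  B01AC: ANTIPLATELET_NON_ASPIRIN
  B01AC06: ASPIRIN
  # anticoagulants: vitamin-K antagonists, heparins, direct inhibitors
  B01AA: ANTICOAGULANT
  B01AB: ANTICOAGULANT
  B01AE: ANTICOAGULANT
  B01AF: ANTICOAGULANT
  B01AX05: ANTICOAGULANT
  # systemic corticosteroids
  H02AB: CORTICOSTEROID
  # selective serotonin reuptake inhibitors
  N06AB: SSRI
  # proton pump inhibitors
  A02BC: PPI

aliases:
  ibuprofen: M01AE01
  naproxen: M01AE02
  ketoprofen: M01AE03
  diclofenac: M01AB05
  indometacin: M01AB01
  mefenamic acid: M01AG01
  celecoxib: M01AH01
  etoricoxib: M01AH05
  aspirin: B01AC06
  acetylsalicylic acid: B01AC06
  clopidogrel: B01AC04
  ticlopidine: B01AC05
  prasugrel: B01AC22
  ticagrelor: B01AC24
  warfarin: B01AA03
  phenprocoumon: B01AA04
  acenocoumarol: B01AA07
  heparin: B01AB01
  dalteparin: B01AB04
  enoxaparin: B01AB05
  nadroparin: B01AB06
  dabigatran: B01AE07
  rivaroxaban: B01AF01
  apixaban: B01AF02
  edoxaban: B01AF03
  fondaparinux: B01AX05
  betamethasone: H02AB01
  dexamethasone: H02AB02
  methylprednisolone: H02AB04
  prednisolone: H02AB06
  prednisone: H02AB07
  triamcinolone: H02AB08
  hydrocortisone: H02AB09
  cortisone: H02AB10
  deflazacort: H02AB13
  fluoxetine: N06AB03
  citalopram: N06AB04
  paroxetine: N06AB05
  sertraline: N06AB06
  fluvoxamine: N06AB08
  escitalopram: N06AB10
  omeprazole: A02BC01
  pantoprazole: A02BC02
  lansoprazole: A02BC03
  rabeprazole: A02BC04
  esomeprazole: A02BC05

# mg prednisone-equivalent per mg of drug (standard equipotency table:
# 5 mg prednisone = 5 mg prednisolone = 4 mg methylprednisolone
# = 0.75 mg dexamethasone = 0.6 mg betamethasone = 20 mg hydrocortisone
# = 25 mg cortisone = 4 mg triamcinolone = 6 mg deflazacort)
corticosteroid_potency:
  H02AB01: 8.3333333333   # betamethasone
  H02AB02: 6.6666666667   # dexamethasone
  H02AB04: 1.25           # methylprednisolone
  H02AB06: 1.0            # prednisolone
  H02AB07: 1.0            # prednisone
  H02AB08: 1.25           # triamcinolone
  H02AB09: 0.25           # hydrocortisone
  H02AB10: 0.2            # cortisone
  H02AB13: 0.8333333333   # deflazacort

# minimum daily dose (native unit of the product) counted as therapeutic
# anticoagulation; doses below are treated as thromboprophylaxis.
anticoagulant_thresholds:
  B01AA: 0.5        # any maintenance VKA dose is therapeutic (mg/day)
  B01AB01: 15000    # unfractionated heparin, IU/day
  B01AB04: 7500     # dalteparin, IU/day (prophylaxis 2500-5000)
  B01AB05: 80       # enoxaparin, mg/day (prophylaxis 20-40)
  B01AB06: 5700     # nadroparin, IU/day
  B01AE07: 300      # dabigatran, mg/day (prophylaxis 150-220)
  B01AF01: 15       # rivaroxaban, mg/day (prophylaxis 10)
  B01AF02: 10       # apixaban, mg/day (prophylaxis 5)
  B01AF03: 30       # edoxaban, mg/day
  B01AX05: 5        # fondaparinux, mg/day (prophylaxis 2.5)

limits:
  aspirin_low_dose_max: 325   # mg/day
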