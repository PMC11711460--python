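# Default 19-region vocabulary: 18 current administrative regions of mainland
# Finland plus the former region of Ceded Karelia. Census sizes are
# approximate current male+female population counts (used only as relative
# weights). "east" is a 0 (far west) .. 1 (far east) coordinate used by the
# synthetic generator to inject east-west clines. Adjacency is geographic
# neighbourhood used for low-coverage regional averaging.
regions:
  UUS: {name: Uusimaa,              census: 1700000, east: 0.45}
  SWF: {name: Southwest Finland,    census: 480000,  east: 0.05}
  SAT: {name: Satakunta,            census: 215000,  east: 0.10}
  TAV: {name: Tavastia Proper,      census: 170000,  east: 0.30}
  PIR: {name: Pirkanmaa,            census: 520000,  east: 0.30}
  PAI: {name: "Päijät-Häme", census: 205000, east: 0.50}
  KYM: {name: Kymenlaakso,          census: 162000,  east: 0.65}
  SKA: {name: South Karelia,        census: 127000,  east: 0.80}
  SSA: {name: Southern Savonia,     census: 132000,  east: 0.80}
  NSA: {name: North Savonia,        census: 248000,  east: 0.85}
  NKA: {name: North Karelia,        census: 162000,  east: 1.00}
  CFI: {name: Central Finland,      census: 272000,  east: 0.50}
  SOS: {name: South Ostrobothnia,   census: 192000,  east: 0.15}
  OST: {name: Ostrobothnia,         census: 176000,  east: 0.05}
  CO:  {name: Central Ostrobothnia, census: 68000,   east: 0.10}
  NOS: {name: North Ostrobothnia,   census: 415000,  east: 0.60}
  KAI: {name: Kainuu,               census: 71000,   east: 0.90}
  LAP: {name: Lapland,              census: 177000,  east: 0.55}
  CKA: {name: Ceded Karelia,        census: 30000,   east: 1.00}
adjacency:
  UUS: [SWF, TAV, PAI, KYM]
  SWF: [UUS, SAT, TAV, PIR]
  SAT: [SWF, PIR, SOS, OST]
  TAV: [SWF, UUS, PIR, PAI]
  PIR: [SAT, SWF, TAV, PAI, CFI, SOS]
  PAI: [UUS, TAV, PIR, CFI, SSA, KYM]
  KYM: [UUS, PAI, SSA, SKA]
  SKA: [KYM, SSA, NKA, CKA]
  SSA: [PAI, KYM, SKA, NSA, NKA, CFI]
  NSA: [SSA, NKA, CFI, NOS, KAI]
  NKA: [SKA, SSA, NSA, KAI, CKA]
  CFI: [PIR, PAI, SSA, NSA, SOS, CO, NOS]
  SOS: [SAT, PIR, CFI, OST, CO]
  OST: [SAT, SOS, CO]
  CO:  [OST, SOS, CFI, NOS]
  NOS: [CO, CFI, NSA, KAI, LAP]
  KAI: [NOS, NSA, NKA, LAP]
  LAP: [NOS, KAI]
  CKA: [SKA, NKA]
special:
  foreign_code: FOREIGN
  # The Aland islands are recognised but excluded from the regional analyses
  # by default (single low-coverage island region).
  excluded_by_default: [ALA]
  extra_codes:
    ALA: {name: "Åland", census: 30000, east: 0.00}
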