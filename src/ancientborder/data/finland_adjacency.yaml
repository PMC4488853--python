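# Adjacency of the 13 Finnish subpopulations (county-level codes).
# MI Mikkeli, CF Central Finland, KU Kuopio, KY Kymenlaakso, NC Northern
# Carelia, OU Oulu, LA Lappi, AL Aland, TU Turku, HA Hame, VA Vaasa,
# UU Uusimaa, LMO Larsma.  Edges encode ordinary geographic county
# neighbourhood (AL-TU across the archipelago).
nodes: [MI, CF, KU, KY, NC, OU, LA, AL, TU, HA, VA, UU, LMO]
edges:
  - [AL, TU]
  - [TU, UU]
  - [TU, HA]
  - [TU, VA]
  - [UU, HA]
  - [UU, KY]
  - [HA, VA]
  - [HA, KY]
  - [HA, MI]
  - [HA, CF]
  - [VA, CF]
  - [VA, LMO]
  - [VA, OU]
  - [LMO, OU]
  - [KY, MI]
  - [MI, CF]
  - [MI, KU]
  - [MI, NC]
  - [CF, KU]
  - [CF, OU]
  - [KU, NC]
  - [KU, OU]
  - [NC, OU]
  - [OU, LA]
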