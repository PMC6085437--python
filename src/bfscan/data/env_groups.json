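{
  "description": "Ordered keyword rules mapping free-text sample environment metadata to environment groups. The first rule whose keyword occurs in the (lowercased) metadata wins; marine sediments are routed to deep_marine_sediments only when an explicit depth > 1 m below sea floor is stated (built-in depth rule, applied before these rules). Groups groundwater, deep_subsurface, hydrothermal_vents_springs, subsurface_sediments and deep_marine_sediments are classed subsurface; all other groups are surface.",
  "rules": [
    {"contains": ["groundwater", "aquifer"], "group": "groundwater"},
    {"contains": ["deep subsurface", "subsurface rock", "fracture fluid", "borehole", "deep mine"], "group": "deep_subsurface"},
    {"contains": ["hydrothermal", "hot spring", "thermal spring", "geyser", "vent"], "group": "hydrothermal_vents_springs"},
    {"contains": ["subsurface sediment"], "group": "subsurface_sediments"},
    {"contains": ["deep marine sediment"], "group": "deep_marine_sediments"},
    {"contains": ["hypersaline", "saline", "brine", "salt marsh", "solar saltern"], "group": "saline"},
    {"contains": ["surface water", "freshwater", "lake", "river", "stream", "ocean", "seawater", "marine water", "coastal water"], "group": "surface_water"},
    {"contains": ["soil", "rhizosphere", "permafrost", "peat"], "group": "soil"}
  ]
}
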