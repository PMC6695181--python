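# Default species-traits database.
#
# allometric_a / allometric_b parameterise fresh above-ground biomass
# B_fresh = a * (dbh_cm^2 * height_m)^b in kg; growth_dbh is the annual
# diameter increment (cm/yr) of a tree in perfect condition.  Unlisted
# species resolve through group_defaults by trait group.
group_defaults:
  hardwood: {group: hardwood, allometric_a: 0.10, allometric_b: 0.95, growth_dbh: 0.6}
  conifer:  {group: conifer,  allometric_a: 0.08, allometric_b: 0.95, growth_dbh: 0.4}
species:
  Robinia pseudoacacia:   {group: hardwood, allometric_a: 0.11, allometric_b: 0.95, growth_dbh: 0.8}
  Fraxinus excelsior:     {group: hardwood, allometric_a: 0.10, allometric_b: 0.95, growth_dbh: 0.6}
  Elaeagnus angustifolia: {group: hardwood, allometric_a: 0.09, allometric_b: 0.95, growth_dbh: 0.7}
  Cupressus arizonica:    {group: conifer,  allometric_a: 0.08, allometric_b: 0.95, growth_dbh: 0.4}
  Ulmus carpinifolia:     {group: hardwood, allometric_a: 0.10, allometric_b: 0.95, growth_dbh: 0.5}
  Ailanthus altissima:    {group: hardwood, allometric_a: 0.09, allometric_b: 0.95, growth_dbh: 0.9}
  Pinus nigra:            {group: conifer,  allometric_a: 0.08, allometric_b: 0.95, growth_dbh: 0.4}
  Pinus eldarica:         {group: conifer,  allometric_a: 0.08, allometric_b: 0.95, growth_dbh: 0.5}
  Morus alba:             {group: hardwood, allometric_a: 0.11, allometric_b: 0.95, growth_dbh: 0.6}
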