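species,count,carbon_storage_t,net_sequestration_t_yr,pollution_removal_t_yr
Robinia pseudoacacia,240590,9317.89,1486.86,26.29
Fraxinus excelsior,188821,6967.33,910.39,17.72
Elaeagnus angustifolia,153675,3405.93,701.52,15.18
Cupressus arizonica,130009,3002.26,312.29,17.44
Ulmus carpinifolia 'Hollandica',128342,3875.48,271.97,8.46
Ailanthus altissima,107713,2072.22,431.49,6.43
Pinus nigra,94402,1930.57,285.83,11.72
Vitis vinifera,82417,1348.71,287.43,4.17
Pinus eldarica,73773,1202.43,183.2,7.65
Robinia pseudoacacia 'Umbraculifera',69096,885.40,253.2,3.36
Morus alba,63579,5861.11,632.4,9.78
Other species (37),595149,24918.79,4896.26,71.86
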