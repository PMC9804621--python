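class_code,class_name,pooled_category
111,Continuous urban fabric,other
112,Discontinuous urban fabric,other
121,Industrial or commercial units,other
122,Road and rail networks and associated land,other
123,Port areas,other
124,Airports,other
131,Mineral extraction sites,other
132,Dump sites,other
133,Construction sites,other
141,Green urban areas,other
142,Sport and leisure facilities,other
211,Non-irrigated arable land,agriculture
212,Permanently irrigated land,agriculture
213,Rice fields,agriculture
221,Vineyards,agriculture
222,Fruit trees and berry plantations,agriculture
223,Olive groves,agriculture
231,Pastures,agriculture
241,Annual crops associated with permanent crops,agriculture
242,Complex cultivation patterns,agriculture
243,Land principally occupied by agriculture with significant areas of natural vegetation,agriculture
244,Agro-forestry areas,agriculture
311,Broad-leaved forest,deciduous_forest
312,Coniferous forest,other_forest
313,Mixed forest,other_forest
321,Natural grasslands,mountain_vegetation
322,Moors and heathland,mountain_vegetation
323,Sclerophyllous vegetation,other
324,Transitional woodland-shrub,other_forest
331,Beaches dunes sands,other
332,Bare rocks,sparse_mountain
333,Sparsely vegetated areas,sparse_mountain
334,Burnt areas,other
335,Glaciers and perpetual snow,other
411,Inland marshes,wetlands
412,Peat bogs,wetlands
421,Salt marshes,other
422,Salines,other
423,Intertidal flats,other
511,Water courses,inland_waters
512,Water bodies,inland_waters
521,Coastal lagoons,other
522,Estuaries,other
523,Sea and ocean,other
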