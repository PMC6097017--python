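species,growth_form,life_form_group
Hydrocharis morsus-ranae,lemnid,free-floating
Lemna minor,lemnid,free-floating
Spirodela polyrhiza,lemnid,free-floating
Ceratophyllum demersum,ceratophyllid,free-floating
Stratiotes aloides,ceratophyllid,free-floating
Utricularia australis,ceratophyllid,free-floating
Utricularia intermedia,ceratophyllid,free-floating
Utricularia minor,ceratophyllid,free-floating
Utricularia ochroleuca,ceratophyllid,free-floating
Utricularia vulgaris,ceratophyllid,free-floating
Callitriche hermaphroditica,elodeid,rhizophyte
Elodea canadensis,elodeid,rhizophyte
Myriophyllum alterniflorum,elodeid,rhizophyte
Myriophyllum sibiricum,elodeid,rhizophyte
Myriophyllum verticillatum,elodeid,rhizophyte
Najas flexilis,elodeid,rhizophyte
Potamogeton alpinus,elodeid,rhizophyte
Potamogeton berchtoldii,elodeid,rhizophyte
Potamogeton compressus,elodeid,rhizophyte
Potamogeton gramineus,elodeid,rhizophyte
Potamogeton gramineus x perfoliatus,elodeid,rhizophyte
Potamogeton obtusifolius,elodeid,rhizophyte
Potamogeton perfoliatus,elodeid,rhizophyte
Potamogeton praelongus,elodeid,rhizophyte
Ranunculus peltatus,elodeid,rhizophyte
Ranunculus peltatus ssp. baudotii,elodeid,rhizophyte
Ranunculus peltatus ssp. peltatus,elodeid,rhizophyte
Callitriche cophocarpa,elodeid,rhizophyte
Callitriche palustris,elodeid,rhizophyte
Juncus bulbosus,elodeid,rhizophyte
Sparganium natans,elodeid,rhizophyte
Elatine hydropiper,isoetid,rhizophyte
Elatine orthosperma,isoetid,rhizophyte
Elatine triandra,isoetid,rhizophyte
Eleocharis acicularis,isoetid,rhizophyte
Isoetes echinospora,isoetid,rhizophyte
Isoetes lacustris,isoetid,rhizophyte
Littorella uniflora,isoetid,rhizophyte
Lobelia dortmanna,isoetid,rhizophyte
Ranunculus reptans,isoetid,rhizophyte
Subuluria aquatica,isoetid,rhizophyte
Nuphar lutea,floating-leaved,rhizophyte
Nuphar lutea x pumila,floating-leaved,rhizophyte
Nuphar pumila,floating-leaved,rhizophyte
Nymphaea alba ssp. alba,floating-leaved,rhizophyte
Nymphaea alba ssp. candida,floating-leaved,rhizophyte
Nymphaea alba ssp. candida x tetragona,floating-leaved,rhizophyte
Nymphaea tetragona,floating-leaved,rhizophyte
Persicaria amphibia,floating-leaved,rhizophyte
Potamogeton natans,floating-leaved,rhizophyte
Sagittaria natans,floating-leaved,rhizophyte
Sparganium angustifolium,floating-leaved,rhizophyte
Sparganium gramineum,floating-leaved,rhizophyte
Sagittaria natans x sagittifolia,floating-leaved,rhizophyte
Alisma plantago-aquatica,helophyte,helophyte
Alopecurus aequalis,helophyte,helophyte
Butomus umbellatus,helophyte,helophyte
Eleocharis mamillata,helophyte,helophyte
Eleocharis palustris,helophyte,helophyte
Equisetum fluviatile,helophyte,helophyte
Glyceria fluitans,helophyte,helophyte
Hippuris vulgaris,helophyte,helophyte
Iris pseudacorus,helophyte,helophyte
Lysimachia thyrsiflora,helophyte,helophyte
Phragmites australis,helophyte,helophyte
Ranunculus lingua,helophyte,helophyte
Sagittaria sagittifolia,helophyte,helophyte
Schoenoplectus lacustris,helophyte,helophyte
Scolochloa festucacea,helophyte,helophyte
Sparganium emersum,helophyte,helophyte
Sparganium erectum,helophyte,helophyte
Typha angustifolia,helophyte,helophyte
Typha latifolia,helophyte,helophyte
Bidens cernua,shore plant,shore plant
Bidens radiata,shore plant,shore plant
Bidens tripartita,shore plant,shore plant
Calla palustris,shore plant,shore plant
Caltha palustris,shore plant,shore plant
Carex acuta,shore plant,shore plant
Carex aquatilis,shore plant,shore plant
Carex diandra,shore plant,shore plant
Carex elata,shore plant,shore plant
Carex lasiocarpa,shore plant,shore plant
Carex paniculata,shore plant,shore plant
Carex pseudocyperus,shore plant,shore plant
Carex rostrata,shore plant,shore plant
Carex vesicaria,shore plant,shore plant
Cicuta virosa,shore plant,shore plant
Cladium mariscus,shore plant,shore plant
Comarum palustre,shore plant,shore plant
Juncus filiformis,shore plant,shore plant
Lycopus europaeus,shore plant,shore plant
Lysimachia vulgaris,shore plant,shore plant
Lythrum salicaria,shore plant,shore plant
Menyanthes trifoliata,shore plant,shore plant
Phalaris arundinacea,shore plant,shore plant
Rumex aquaticus,shore plant,shore plant
Scirpus sylvaticus,shore plant,shore plant
Thelypteris palustris,shore plant,shore plant
Chara globularis,charophyte,rhizophyte
Nitella confervacea,charophyte,rhizophyte
Nitella flexilis,charophyte,rhizophyte
Nitella opaca,charophyte,rhizophyte
Nitella wahlbergiana,charophyte,rhizophyte
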