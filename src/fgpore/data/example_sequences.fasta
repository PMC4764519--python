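>nsp1
FSFGKTTNGPAETTFSFGTANKTESSSTFSFGGTSNSNGQSNFSFGSAKPANSEPPFSFG
SQQGATSGSQFSFGTTNATENPKNFSFGSSTGTQSQGTFSFGNAKTESQSQTFSFGPSAK
QGQTTEFSFGPNSQGGGQNAFSFGPTGNTGTGSSFSFGNEQSQQGTKSFSFGNSTENKST
STFSFGETTQPTKNGGFSFGNQTAESKSNQFSFGAQAEATSSKGFSFGSENSSTANKNFS
FGAQSNTGASAPFSFGSGTQGSTNQTFSFGSSQATTSNGGFSFGNQSEPNKGNQFSFGQG
TSPNSNQSFSFGANSTNQASTTFSFGSAKQAPESQGFSFGPNTGGSNSTQFSFGSNSGKT
NESTFSFGNSEQSSKPNGFSFGQGNSQSQQSAFSFGGNQPPAQGQGFSFGQATGNGSQGT
FSFGTQSATSTSSSFSFGGSNGNNAGQAFSFGSNETGKSSSPFSFGAPNGSNTQGPFSFG
GQTEQSQKGSFSFGQAGGNTETGKFSFGTGGQTKSEGGFSFGGTGGNNSGNNFSFGATNT
KNGPTEFSFGSATTGTSQTSFSFGPPSAPGGSATFSFGSSPTNSNTNSFSFGNGTEPTGK
AN
>nup49
FSFGTKNASQQSEGFSFGQESNTKNGGGFSFGTTTQNTKAESFSFGTNKSPPSPETFSFG
NNNSPGGTSAFSFGAQGAQTSTQQFSFGGATQQSTQAGFSFGNKSQAESTQQFSFGSNQS
GQTNKEFSFGTPQGTAGNAGFSFGNSTGSGKAAEFSFGNKGSQEQAAQFSFGKNTGSSPQ
EAFSFGAAGTSGTPGGFSFGPNNGESTTQKFSFGGQNQNNSNQGFSFGTSGSGATATNFS
FGGNPATSAESKFSFGNSKAATGSSEFSFGSANQNAPTTGFSFGPAPTSGEKGGFSFGSN
NAQGSSNQFSFGNQNQSQSGSPFSFGTASNTNAGQN
>nup57
FSFGQATQATQSTSFSFGTNTSTNNQSAFSFGSQNQGNNATNFSFGEGKNSSGTTAFSFG
SSGGANSSTTFSFGSQAGETGKAPFSFGANSSTATGQQFSFGENTNNKQAASFSFGSTTG
SNAQANFSFGSPATSTSQAQFSFGQTGASSSSSGFSFGGGGGTTEKNTFSFGTSSEASNS
QKFSFGTGTNASQPNSFSFGTAQTSGGPGGFSFGNPESTNSKTSFSFGGASGENGNKAFS
FGTSTTGGQPPTFSFGTAPGGASGSAFSFGTPNQSTAPNTFSFGNGNGPTTNSNFSFGQT
QNSQASTNFSFGKTPAASNEGNFSFGSTSGGEASSKFSFGSSATNSGSPSFSFGSTGTAE
KGNT
>nup42
FSFGNGAGSQGSQSFSFGSAGPSQSPTAFSFGTETKPNQSTSFSFGNNKPEASGTGFSFG
GNNTQTTGQSFSFGNKGPQESPNNFSFGQTNGSGESKSFSFGGSTTSPSTSAFSFGNSKQ
ATSAESFSFGSTTQANSGSSFSFGQGSTGQQSATFSFGSPKSGSENSAFSFGGQSASNPS
TTFSFGNNGGSGGKAEFSFGSGQNASSTTAFSFGKSAGSETSQNFSFGTGNTPSQEGKFS
FGNPAKPTGNESFSFGATATKANENQFSFGSSNATGSGQGFSFGQAGSSGTGNAFSFGSS
GSANKGEPFSFGTSTATAANQTFSFGQGGNQSGSTPFSFGNGNTNQKEQSFSFGNTNTAG
SNTSFSFGSSNNGTTANQFSFGQEKNGTGGGTFSFGSGNNGQPKGEFSFGGTGTTNTSNA
>nup159
FSFGKQSQPNEPTQFSFGSTGSAQSSSTFSFGNGQNTNAKTEFSFGASSSQTSTGTFSFG
TAQPQGTGGQFSFGQTQETPKGGPFSFGTTSQPAATASFSFGTGQGQSSSSAFSFGPATS
SGTAQNFSFGGTQSKSGSEQFSFGGEQGTGAGKSFSFGTQNTQQQSGAFSFGPQSNTTSN
SGFSFGQAGQTSTQGGFSFGKSNSGTGSNEFSFGQGGSTEAKGGFSFGSNGSQENSKNFS
FGGNTTQGAGNTFSFGGETTKSSANGFSFGNSTSTTGTSSFSFGQTQQKAEGPNFSFGGS
PSPSQNSPFSFGGGTSGTSKQEFSFGESQNKGASATFSFGGQQSTTGTNSFSFGSNSNGS
GGTTFSFGQQGQQGSQQSFSFGPAQQTSSTAGFSFGGSGSNQNTSGFSFGPSQQNSGNGA
FSFGTPNQETQKNTFSFGENNKATTTPAFSFGGGEAKNTPNPFSFGANSSTGTNPSFSFG
NGNGGGGTGTFSFGSSAPGNSNNQFSFGGNKPTTESTGFSFGGGSTSSAAGTFSFGGTTG
GAQQNNFSFGQGQTSTSTQTFSFGANQNTSPATNFSFGNNSPQQNGSAFSFGTGTAPAST
STFSFGQSKANQEPNGFSFGTQSQTTQSSAFSFGENKQANNSGTFSFGGSNGGTNGGTFS
FGEKQPTNTQSNFSFGTGEAGSKGSSFSFGAGTPNTGSSN
>nup1
FSFGQTNNPNGPSNFSFGAGNATGNQSGFSFGTASGNSSTQTFSFGETGQANPKQAFSFG
TKGNNTSAESFSFGKEGSQSAGNSFSFGQNNPGASSGTFSFGSQQNKGQATEFSFGGSGS
QKTNNEFSFGSSPSESQGKSFSFGGASNQGTGGQFSFGSESTGTQNKAFSFGQQKNGNSP
GEFSFGQGQAAAGGTAFSFGGPKGNEATTTFSFGTQNTPTGTTQFSFGGGTPSSPPNAFS
FGGQAGGQTGNGFSFGSTGQNSGTSNFSFGQTTSTQTSGSFSFGGSSSANKSEGFSFGQA
GQSEKQPAFSFGQQNTQSSASTFSFGTNNSSGTNAAFSFGSQSTQSQGSGFSFGQTSNTG
EKNQFSFGSKPNSGTNSEFSFGPSGNSPQSPNFSFGSGEGTNTKSPFSFGNTGQSSAPSA
FSFGTGPNATASTTFSFGASNSNPTQSNFSFGKESQNSSQPSFSFGNSSTTKAAETFSFG
GTQQSPATNGFSFGSSTGSAGSSNFSFGQNQKPATGTEFSFGQSPSQTQQQSFSFGGSSK
EQSQGQFSFGASNQGTSNGGFSFGAQTNTNSGNSFSFGQTSSQSGANQFSFGSASGNSET
PKFSFGSNSTKNENAAFSFGSATASGTTGGFSFGTQTEKAGQGGFSFGTNPQSAPGTAFS
FGQSGKTTESGQFSFGTQTSESSGTKFSFGTGEGTSQAKPFSFGSNTKGSGPENFSFGNT
QTNAQSSNFSFGKSGSTNSQENFSFGSNTGPSSGQTFSFGASPPASASQTFSFGGNGQGQ
QTQPFSFGQNSSQNASPPFSFGSGTPPPGGNSFSFGQASQGNSGAQFSFGATEGATQPAK
FSFGGPTASTEANKFSFGTPTGSNGTTTFSFGGSAPGASNSNFSFGEQATKSSSTNFSFG
ESQGAKGAQNFSFGSPTGASSQGTFSFGNTNNNGTSPSFSFGKQQESNQGTNFSFGTTSS
SNSQTGFSFGNKSPQGQESQFSFGSPTGNTQPSSFSFGTSENSGGAKTFSFGESGQKPSS
TQFSFGGSQQPGSQTNFSFGEQKTTSGSTP
>nup60
FSFGNTGTSAPSSGFSFGSQSTTGGNATFSFGGNGGNQQTTGFSFGGGTEGNTQKGFSFG
QNNSPNEKNTFSFGGNSAPSSANGFSFGTQSSTGKAESFSFGTGSSGATGSQFSFGKNSN
ENNTNTFSFGGKGGQQSSENFSFGTTTTSSGQSAFSFGGGPTSAGNTNFSFGQNQKPETG
AQFSFGTTPQSQKGETFSFGTTASAQTNNGFSFGTSSQTGGQSTFSFGNSQSTGGGKEFS
FGESSSTTQKQSFSFGSGNQPTASQQFSFGNEGKQPSAQSFSFGTSQQNTSPPTFSFGAQ
SNPGNGPNFSFGSASENKGAPGFSFGNNTQSNSQSGFSFGTNPTQGSTNSFSFGGSANGG
QSAAFSFGPPANQKPQAEFSFGGSTETTKSTAFSFGGTSAGATSNSFSFGQTSTGQGNQS
FSFGSTGEGNKGQTFSFGGTSPKSTESNFSFGTGTQNGPKNEFSFGKTPGAATAENFSFG
QSKSQGEASQFSFGNTQTQQTTSGFSFGNAPPSGSESKFSFGQASQSTGQQT
>nup100
FSFGPQGTGKNSAEFSFGNSGTGANSGSFSFGTKEAGQTSPGFSFGQGNTGQNEKTFSFG
APNSSGQSAAFSFGNTNSSNGKQEFSFGEAAGKNGNPNFSFGSEKNTQQTTNFSFGSTEN
QANTKNFSFGQGSGSTAGAGFSFGTNNSTNTAQTFSFGSQKNNNEAATFSFGQNGQNPSS
GSFSFGGTPTNTTQQSFSFGQSNTSSSASTFSFGSSSGSGSAGAFSFGTNAQTAGAGQFS
FGSGTSKQEAGSFSFGGGQSNTENKGFSFGESSTGTSKGSFSFGSTSPQSTTSAFSFGTN
ETTAKSTSFSFGNGSGSGKQEGFSFGGSTSQQNTSSFSFGEKSTQANTQSFSFGSPSGST
NTSSFSFGSQQNNNQQSGFSFGEAKGATTGQGFSFGQTSGSGNANTFSFGNQASPNTSTS
FSFGTNSGGNTGASFSFGTGPGNNKEANFSFGSKEGTSQSAAFSFGSQTSETGKGTFSFG
QKGTQSTGQEFSFGANPSSTGEKTFSFGGTSGSTPNQNFSFGAPNSNEKAPTFSFGSAAT
TSQQNQFSFGTGSGNGSQSGFSFGTGSNAANGNPFSFGASNSPASSQSFSFGNGGNSPGP
SNFSFGSGTGQTQSGTFSFGPNGSKASEGSFSFGSQTQGTNNSSFSFGNSQSNSNNGAFS
FGATGQGNSTQNFSFGSANQANTTQSFSFGETTKQGTTAGFSFGENTQSGNNKNFSFGQS
KSSETGPGFSFGTGTTQTSSQSFSFGNNSTANKSETFSFGTQTANNGSNSFSFGSSQQET
GATKFSFGNTEPTQTPKNFSFGQTGSSTNTNSFSFGTAGPEKTANTFSFGSSQTPTGSTS
FSFGTSGNSTSTKEFSFGQTAASQATSGFSFGAPTASTQGGGFSFGQSTNSQPSGAFSFG
PSGNASSNQGFSFGGTTTSPSGSTFSFGQSQQTGSQSNFSFGGTETSKGNPG
>nup116
FSFGTSQQNTTSNNFSFGSAKNEQQTSSFSFGTGQKGGGETSFSFGAGASGGQTSNFSFG
TQTNNAQTNSFSFGTAGGTGTPNSFSFGQSQPNGTPQTFSFGPPTTTASQKEFSFGKTES
STTTTGFSFGSSNKESAAGSFSFGGSNSTTASGSFSFGATNKTNTQQEFSFGNGAEKGNS
GGFSFGPAQAKTGETNFSFGSKQTQEGAASFSFGSTKANSSQGEFSFGTSEGGPKTQGFS
FGSQTGTPTGPNFSFGGTSKTTSQSEFSFGNSTQSSQSSSFSFGKSESSNGGQQFSFGNN
KTNSTSGEFSFGANTKTEASTSFSFGTKNASENAQQFSFGGTTATPANTQFSFGQQGSQT
AGTSFSFGQGTEKAPQTAFSFGASPNSQSAQNFSFGSKSGESSSGSFSFGPSTGSATQGQ
FSFGTSASGTASNNFSFGNTQQSQSTTSFSFGQAGGSSTAQTFSFGNTPPGANKSEFSFG
SGTSNPGSPTFSFGSNEGPTTTQKFSFGAPGSNKSGEQFSFGQGSGGKTNEAFSFGNTSN
GTGAGTFSFGTPTGTSSNTPFSFGSNASTGSSGTFSFGKAGSTSENNQFSFGNPAQTQTA
AQFSFGQSAQGTGPGTFSFGTSNSGNGSAGFSFGGTGNSSSGGSFSFGPNQESPAGTKFS
FGPQASTGAGQSFSFGTNSGKTNPSEFSFGGPKESGSAPGFSFGGPGSTTGTSSFSFGTQ
STTSQPGAFSFGGQNAGQAGGTFSFGANQQGTQSSAFSFGNQNSQKSETGFSFGPQSAQG
STSQFSFGTATPTNEKQGFSFGQSTSSNNTGSFSFGQGNEQNSGKNFSFGQAGKSSNANE
FSFGNQGTSANSATFSFGNQSKTAEGGSFSFGTSTSQQSNPNFSFGTNASTSSAGGFSFG
PTTKATATEGFSFGTQPTQTGNTQFSFGSSGSQQSGSQFSFGSSTSNGTSAAFSFGKEAT
NGQQPAFSFGTSSGEKNQSSFSFGQSTSSSPGQSFSFGSQSGQNQTPNFSFGENQSSGSN
SKFSFGGGSKSGEAQPFSFGKEGGSASSGQFSFGQGSGKGAESPFSFGEQTKNTSNNT
>nup145
FSFGSKNPSEQATNFSFGKQESTQSPTGFSFGPKAQESGTQSFSFGQTTKSSESGGFSFG
SNPNPQTSAQFSFGKNSNQPQTEGFSFGGGKESQQGGNFSFGNQQQNNPGGQFSFGQAQE
NNTKSNFSFGSTSSSSSKQEFSFGTTTGGGQTSGFSFGPPANSNTQSAFSFGAGSSQQAP
AGFSFGTQGKGGNEAGFSFGSSTGSGQGQSFSFGGNQSTGTTTAFSFGAKGTGETNQTFS
FGSAQNQPQSNQFSFGNKTAENQQSQFSFGTEASPTSQKNFSFGNNNQGASPGGFSFGSN
NSNSAGATFSFGSTTKGQQAESFSFGTKQEQTTSNAFSFGGTQSTSTAAAFSFGNAGGAS
GTTTFSFGQEGPQPNNTKFSFGNSTGSQGPSTFSFGQESKAPNGTTFSFGTGQGGASTQN
FSFGTGQGQQQNTNFSFGNQNGGTSQSNFSFGANTGQKSQEGFSFGPSQTPTNGATFSFG
KTNEASTSGGFSFGAGGSNSPGGTFSFGQNSKGEPGGSFSFGQTKQEATAANFSFGSQAS
STSGASFSFGTSASSNEKGTFSFGSNAAGKSSEGFSFGPTPAPSSAQGFSFGTSTEKGQS
SSFSFGGTTNSASQQPFSFGGSTSTQGTTPFSFGTNGEQGSKAN
>nup2
FSFGNTNQAQTQTSFSFGNTPQNNENKGFSFGTSNEKTQSSNFSFGQPGGKQENTAFSFG
NNEGNTPSQKFSFGENKQQNGNGSFSFGNQTAANGSNSFSFGSPKGQTSGEGFSFGNGNK
TTTGEGFSFGATSAPQTSSQFSFGNNSSTGSNPNFSFGTAQTQESKQGFSFGQSSGTNQS
AGFSFGETQGNKGNTTFSFGQKENSATTANFSFGGSTSASSPSQFSFGNPEKSTSQAQFS
FGTTQSTAAPQQFSFGQNQPTQKSEQFSFGEASPSTKSTTFSFGKTESTNNGQSFSFGNP
GGANEKQNFSFGQASTEKTPAAFSFGNTQTSTGNSGFSFGETNTSKGPSAFSFGNQTNQN
TQSTFSFGQKANGASGSEFSFGNQPNGEPKQPFSFGQNAENKQTSSFSFGGTSQSGQGQN
FSFGNKGGATESTQFSFGQNAGTTQSQSFSFGKGASGTSEGTFSFGKNEQSSQSGAFSFG
STTKGQAQESFSFGKQEAQQNGSNFSFGSATTSTPQAGFSFGANSKAGNSENFSFGSQTK
STATSEFSFGTQTTPGSTANFSFGQNNNGTPSANFSFGAAKNGSNEPGFSFGSSQTTSSN
STFSFGSSGKQSQATEFSFGQSKQSGTAEGFSFGQTSNPTNANTFSFGTNGEAQTSSKFS
FGNATQQKAESQFSFGTSNTEKQTAGFSFGGQSTQAQNPPFSFGEQKGSQSNQS
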