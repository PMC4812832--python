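food_id,name,kcal_per_unit,ingredients
F001,cheeseburger,550,bun;beef patty;cheese;ketchup
F002,lettuce burger,480,bun;beef patty;lettuce;tomato
F003,bacon burger,650,bun;beef patty;cheese;bacon
F004,veggie burger,380,bun;bean patty;lettuce;tomato
F005,caesar salad,320,romaine;croutons;parmesan;caesar dressing
F006,garden salad,180,romaine;tomato;cucumber;vinaigrette
F007,chicken salad,400,romaine;grilled chicken;tomato;vinaigrette
F008,margherita pizza slice,280,dough;tomato sauce;mozzarella;basil
F009,pepperoni pizza slice,330,dough;tomato sauce;mozzarella;pepperoni
F010,spaghetti bolognese,560,spaghetti;tomato sauce;ground beef;parmesan
F011,chicken burrito,620,tortilla;rice;grilled chicken;beans;salsa
F012,bean burrito,520,tortilla;rice;beans;salsa;cheese
F013,oatmeal with fruit,290,oats;milk;banana;honey
F014,scrambled eggs toast,350,eggs;butter;toast
F015,pancakes with syrup,520,flour;eggs;milk;maple syrup
F016,yogurt parfait,240,yogurt;granola;berries
F017,turkey sandwich,420,bread;turkey;lettuce;mayonnaise
F018,grilled cheese sandwich,440,bread;cheese;butter
F019,chicken noodle soup,250,chicken;noodles;carrot;celery;broth
F020,sushi roll,300,rice;nori;salmon;avocado
F021,apple,95,apple
F022,banana,105,banana
F023,potato chips bag,160,potato;vegetable oil;salt
F024,chocolate bar,230,cocoa;sugar;milk solids
F025,trail mix pack,190,peanuts;raisins;almonds;chocolate chips
F026,soda can,140,carbonated water;sugar;caramel color
F027,granola bar,120,oats;honey;almonds
F028,cookie,150,flour;butter;sugar;chocolate chips
F029,carrot sticks,50,carrot
F030,string cheese,80,mozzarella
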